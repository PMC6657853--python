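"""Schur-complement linear solver for slice/chamber-structured FEM systems.

Both the homogenized and layered discretizations share one algebraic
structure: the global backward-Euler operator is block diagonal over
cross-section blocks (one slice, or one two-level chamber), plus a sparse
surface operator on the sliver unknowns, which are a fixed subset of each
block's nodes and the only inter-block coupling.  Eliminating the non-sliver
interior of every block (batched dense factorizations) leaves a small sparse
Schur system on the sliver strip.  Activated-fold reactions perturb only a
few blocks per time step, so only those blocks and the Schur factorization
are refreshed while the effector field is non-negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class BlockSchurSolver:
    """Solve A x = b with A = blockdiag(A_b) + scatter(A_sliver).

    Parameters
    ----------
    base_blocks : (B, mb, mb) array
        Constant part of each block's dense operator.  Block b owns global
        dofs [b*mb, (b+1)*mb).
    s_local : (n_sb,) int array
        Local indices (within a block) of the block's sliver nodes; global
        sliver dof of block b, slot q is b*n_sb + q.
    A_sliver : sparse (B*n_sb, B*n_sb)
        Sliver-surface operator in global sliver numbering (couples blocks).
    """

    def __init__(self, base_blocks: np.ndarray, s_local: np.ndarray,
                 A_sliver: sp.spmatrix):
        self.B, self.mb, _ = base_blocks.shape
        self.s = np.asarray(s_local, dtype=np.int64)
        self.n_sb = len(self.s)
        mask = np.ones(self.mb, dtype=bool)
        mask[self.s] = False
        self.i = np.nonzero(mask)[0]
        self.mi = len(self.i)
        self.base = base_blocks
        self.A_sliver = A_sliver.tocsr()
        self._diag_updates: dict[int, np.ndarray] = {}

        # Precompute the COO pattern of the Schur matrix: sliver operator
        # entries plus a dense n_sb x n_sb block per cross-section block.
        Asl = self.A_sliver.tocoo()
        nS = self.B * self.n_sb
        bd_rows = (np.arange(self.B)[:, None, None] * self.n_sb
                   + np.arange(self.n_sb)[None, :, None])
        bd_rows = np.broadcast_to(bd_rows, (self.B, self.n_sb, self.n_sb)).ravel()
        bd_cols = (np.arange(self.B)[:, None, None] * self.n_sb
                   + np.arange(self.n_sb)[None, None, :])
        bd_cols = np.broadcast_to(bd_cols, (self.B, self.n_sb, self.n_sb)).ravel()
        self._schur_rows = np.concatenate([bd_rows, Asl.row])
        self._schur_cols = np.concatenate([bd_cols, Asl.col])
        self._sliver_data = Asl.data
        self._nS = nS

        self._AII_inv = np.empty((self.B, self.mi, self.mi))
        self._W = np.empty((self.B, self.mi, self.n_sb))
        self._ASI = np.empty((self.B, self.n_sb, self.mi))
        self._Sblk = np.empty((self.B, self.n_sb, self.n_sb))
        self._factor_blocks(range(self.B))
        self._refactor_schur()

    # -- factorization ----------------------------------------------------
    def _block_matrix(self, b: int) -> np.ndarray:
        A = self.base[b]
        upd = self._diag_updates.get(b)
        if upd is None:
            return A
        A = A.copy()
        A[np.arange(self.mb), np.arange(self.mb)] += upd
        return A

    def _factor_blocks(self, which) -> None:
        for b in which:
            A = self._block_matrix(b)
            AII = A[np.ix_(self.i, self.i)]
            AIS = A[np.ix_(self.i, self.s)]
            ASI = A[np.ix_(self.s, self.i)]
            ASS = A[np.ix_(self.s, self.s)]
            AII_inv = np.linalg.inv(AII)
            W = AII_inv @ AIS
            self._AII_inv[b] = AII_inv
            self._W[b] = W
            self._ASI[b] = ASI
            self._Sblk[b] = ASS - ASI @ W

    def _refactor_schur(self) -> None:
        data = np.concatenate([self._Sblk.ravel(), self._sliver_data])
        G = sp.coo_matrix((data, (self._schur_rows, self._schur_cols)),
                          shape=(self._nS, self._nS)).tocsc()
        self._G = splu(G)

    def set_diag_updates(self, updates: dict[int, np.ndarray]) -> None:
        """Replace per-block diagonal perturbations and refactor.

        ``updates`` maps block index -> length-mb diagonal addition (e.g.
        dt * k_hyd * E* nodal weights on an activated fold).  Blocks that had
        an update before but are absent now are restored to the base matrix.
        """
        touched = set(updates) | set(self._diag_updates)
        self._diag_updates = {b: np.asarray(v, dtype=float)
                              for b, v in updates.items()}
        if touched:
            self._factor_blocks(sorted(touched))
            self._refactor_schur()

    # -- solve -------------------------------------------------------------
    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve for a global right-hand side (length B*mb)."""
        rb = b.reshape(self.B, self.mb)
        bI = rb[:, self.i]
        bS = rb[:, self.s]
        y = np.matmul(self._AII_inv, bI[:, :, None])[:, :, 0]
        g = (bS - np.matmul(self._ASI, y[:, :, None])[:, :, 0]).ravel()
        xS = self._G.solve(g).reshape(self.B, self.n_sb)
        xI = y - np.matmul(self._W, xS[:, :, None])[:, :, 0]
        out = np.empty_like(rb)
        out[:, self.i] = xI
        out[:, self.s] = xS
        return out.ravel()


def scatter_sliver_matrix(A_local: sp.spmatrix, sliver_to_global: np.ndarray,
                          n_dofs: int) -> sp.csr_matrix:
    """Map a sliver-mesh operator into global dof numbering.

    Coincident sliver-mesh nodes that share a global dof (the theta wrap at
    omega0 = 2*pi) accumulate, which glues the seam.
    """
    A = A_local.tocoo()
    return sp.coo_matrix(
        (A.data, (sliver_to_global[A.row], sliver_to_global[A.col])),
        shape=(n_dofs, n_dofs)).tocsr()
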