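"""Linear-chain conditional random field with L-BFGS training.

Observation features are named, possibly real-valued (word-embedding
weights), and tied to single labels; first-order label-transition weights
plus start/end scores complete the potential.  Training maximizes the
L2-regularized conditional log-likelihood with scipy's L-BFGS-B; the
forward-backward recursions run batched across all (padded) sequences in
log space, so an epoch over a few thousand sentences costs milliseconds.

Everything is deterministic: the feature index is built in first-seen
order, the objective is smooth, and no randomness enters training.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

FeatureSeq = Sequence[dict[str, float]]


class LinearChainCRF:
    def __init__(
        self,
        labels: Sequence[str] = ("B", "I", "E", "O"),
        c2: float = 0.1,
        max_iter: int = 100,
        tol: float = 1e-5,
    ):
        if c2 < 0:
            raise ValueError("c2 must be >= 0")
        self.labels = list(labels)
        self.c2 = c2
        self.max_iter = max_iter
        self.tol = tol
        self.feature_index: dict[str, int] | None = None
        self.W: np.ndarray | None = None  # (F, L) state weights
        self.T: np.ndarray | None = None  # (L, L) transitions
        self.start: np.ndarray | None = None  # (L,)
        self.end: np.ndarray | None = None  # (L,)

    @property
    def is_fitted(self) -> bool:
        return self.W is not None

    # -- design-matrix plumbing ------------------------------------------

    def _build_index(self, X: Sequence[FeatureSeq]) -> None:
        index: dict[str, int] = {}
        for seq in X:
            for feats in seq:
                for name in feats:
                    if name not in index:
                        index[name] = len(index)
        if not index:
            raise ValueError("no features observed")
        self.feature_index = index

    def _design(self, X: Sequence[FeatureSeq]) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Stack all positions row-wise; also return per-sequence lengths."""
        assert self.feature_index is not None
        rows, cols, vals = [], [], []
        lengths = []
        r = 0
        for seq in X:
            lengths.append(len(seq))
            for feats in seq:
                for name, value in feats.items():
                    col = self.feature_index.get(name)
                    if col is not None:
                        rows.append(r)
                        cols.append(col)
                        vals.append(value)
                r += 1
        mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(r, len(self.feature_index))
        )
        return mat, np.asarray(lengths, dtype=int)

    @staticmethod
    def _pad(E_flat: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(positions, L) emissions -> (N, Tmax, L) padded + active mask."""
        N, Tmax, L = len(lengths), int(lengths.max()), E_flat.shape[1]
        emit = np.zeros((N, Tmax, L))
        active = np.zeros((N, Tmax), dtype=bool)
        offset = 0
        for i, n in enumerate(lengths):
            emit[i, :n] = E_flat[offset : offset + n]
            active[i, :n] = True
            offset += n
        return emit, active

    # -- objective --------------------------------------------------------

    def _nll_grad(
        self,
        theta: np.ndarray,
        Xm: sparse.csr_matrix,
        XmT: sparse.csr_matrix,
        lengths: np.ndarray,
        y_flat: np.ndarray,
    ) -> tuple[float, np.ndarray]:
        L = len(self.labels)
        F = Xm.shape[1]
        W = theta[: F * L].reshape(F, L)
        T = theta[F * L : F * L + L * L].reshape(L, L)
        s = theta[F * L + L * L : F * L + L * L + L]
        e = theta[F * L + L * L + L :]

        E_flat = Xm @ W  # (positions, L)
        emit, active = self._pad(E_flat, lengths)
        N, Tmax, _ = emit.shape

        # forward (carry alpha past sequence ends)
        alpha = np.empty_like(emit)
        alpha[:, 0] = s + emit[:, 0]
        for t in range(1, Tmax):
            comp = logsumexp(alpha[:, t - 1][:, :, None] + T[None], axis=1)
            comp += emit[:, t]
            alpha[:, t] = np.where(active[:, t][:, None], comp, alpha[:, t - 1])
        logZ = logsumexp(alpha[:, -1] + e[None], axis=1)

        # backward (beta includes the end score)
        beta = np.empty_like(emit)
        beta[:, -1] = e
        for t in range(Tmax - 2, -1, -1):
            nxt = emit[:, t + 1] + beta[:, t + 1]
            comp = logsumexp(T[None] + nxt[:, None, :], axis=2)
            beta[:, t] = np.where(active[:, t + 1][:, None], comp, beta[:, t + 1])

        # node marginals at real positions, flattened back to (positions, L)
        log_marg = alpha + beta - logZ[:, None, None]
        P = np.exp(log_marg)
        P[~active] = 0.0
        P_flat = P[active]  # ordered row-major: sequence i, then t — matches stacking

        # gold score
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        ends = np.cumsum(lengths) - 1
        pos_idx = np.arange(Xm.shape[0])
        gold = E_flat[pos_idx, y_flat].sum()
        gold += s[y_flat[starts]].sum() + e[y_flat[ends]].sum()
        trans_counts = np.zeros((L, L))
        within = np.ones(Xm.shape[0], dtype=bool)
        within[ends] = False  # last position of each sequence has no outgoing edge
        idx = np.where(within)[0]
        np.add.at(trans_counts, (y_flat[idx], y_flat[idx + 1]), 1)
        gold += (trans_counts * T).sum()

        nll = logZ.sum() - gold + self.c2 * float(theta @ theta)

        # gradients
        Y = np.zeros_like(P_flat)
        Y[pos_idx, y_flat] = 1.0
        grad_W = XmT @ (P_flat - Y)  # (F, L)

        grad_T = -trans_counts
        for t in range(Tmax - 1):
            edge_mask = active[:, t + 1]
            if not edge_mask.any():
                break
            log_edge = (
                alpha[:, t][:, :, None]
                + T[None]
                + (emit[:, t + 1] + beta[:, t + 1])[:, None, :]
                - logZ[:, None, None]
            )
            grad_T += np.exp(log_edge[edge_mask]).sum(axis=0)

        grad_s = P[:, 0].sum(axis=0)
        np.add.at(grad_s, y_flat[starts], -1.0)
        grad_e = P[np.arange(N), lengths - 1].sum(axis=0)
        np.add.at(grad_e, y_flat[ends], -1.0)

        grad = np.concatenate(
            [grad_W.ravel(), grad_T.ravel(), grad_s, grad_e]
        ) + 2.0 * self.c2 * theta
        return nll, grad

    # -- public API -------------------------------------------------------

    def fit(
        self, X: Sequence[FeatureSeq], y: Sequence[Sequence[str]]
    ) -> "LinearChainCRF":
        if len(X) != len(y) or not X:
            raise ValueError("need equally many non-empty X and y sequences")
        label_to_i = {lab: i for i, lab in enumerate(self.labels)}
        self._build_index(X)
        Xm, lengths = self._design(X)
        XmT = Xm.T.tocsr()
        y_flat = np.array(
            [label_to_i[lab] for seq in y for lab in seq], dtype=int
        )
        if len(y_flat) != Xm.shape[0]:
            raise ValueError("label sequences do not match feature sequences")
        L = len(self.labels)
        F = Xm.shape[1]
        theta0 = np.zeros(F * L + L * L + 2 * L)
        result = optimize.minimize(
            self._nll_grad,
            theta0,
            args=(Xm, XmT, lengths, y_flat),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxcor": 10, "ftol": self.tol},
        )
        theta = result.x
        self.W = theta[: F * L].reshape(F, L)
        self.T = theta[F * L : F * L + L * L].reshape(L, L)
        self.start = theta[F * L + L * L : F * L + L * L + L]
        self.end = theta[F * L + L * L + L :]
        return self

    def _emissions(self, seq: FeatureSeq) -> np.ndarray:
        assert self.feature_index is not None and self.W is not None
        E = np.zeros((len(seq), len(self.labels)))
        for t, feats in enumerate(seq):
            for name, value in feats.items():
                col = self.feature_index.get(name)
                if col is not None:
                    E[t] += value * self.W[col]
        return E

    def predict(self, X: Sequence[FeatureSeq]) -> list[list[str]]:
        """Viterbi decoding of the best label sequence per input sequence."""
        if not self.is_fitted:
            raise RuntimeError("predict called on an untrained CRF")
        out: list[list[str]] = []
        for seq in X:
            if not seq:
                out.append([])
                continue
            E = self._emissions(seq)
            n, L = E.shape
            delta = np.empty((n, L))
            back = np.zeros((n, L), dtype=int)
            delta[0] = self.start + E[0]
            for t in range(1, n):
                scores = delta[t - 1][:, None] + self.T
                back[t] = scores.argmax(axis=0)
                delta[t] = scores.max(axis=0) + E[t]
            delta[-1] += self.end
            path = [int(delta[-1].argmax())]
            for t in range(n - 1, 0, -1):
                path.append(int(back[t, path[-1]]))
            path.reverse()
            out.append([self.labels[i] for i in path])
        return out

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        if not self.is_fitted:
            raise RuntimeError("cannot serialize an untrained CRF")
        names = [None] * len(self.feature_index)
        for name, i in self.feature_index.items():
            names[i] = name
        return {
            "labels": self.labels,
            "c2": self.c2,
            "max_iter": self.max_iter,
            "features": names,
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "start": self.start.tolist(),
            "end": self.end.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "LinearChainCRF":
        crf = cls(labels=obj["labels"], c2=obj["c2"], max_iter=obj["max_iter"])
        crf.feature_index = {name: i for i, name in enumerate(obj["features"])}
        crf.W = np.asarray(obj["W"])
        crf.T = np.asarray(obj["T"])
        crf.start = np.asarray(obj["start"])
        crf.end = np.asarray(obj["end"])
        return crf

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LinearChainCRF":
        return cls.from_dict(json.loads(Path(path).read_text()))
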