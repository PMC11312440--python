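"""Covariate design construction: linear, polynomial, categorical and P-spline terms.

Terms are small frozen dataclasses naming a covariate column and how to expand
it.  A fitted :class:`DesignInfo` captures everything needed to rebuild the
design on new data bit-identically (knot vectors, column means, category
levels, standardization constants).

P-spline terms use a cubic B-spline basis with equally spaced interior knots
and a second-order difference penalty.  For identifiability inside a model
that carries its own intercept, the first basis column is dropped and the
remaining columns are centered at their training means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import qr


@dataclass(frozen=True)
class Linear:
    """Raw linear term for a numeric covariate column."""

    name: str


@dataclass(frozen=True)
class Poly:
    """Polynomial term on an internally standardized covariate.

    The covariate is centered and scaled by its training mean/SD before the
    powers are formed, so coefficients refer to the standardized variable.
    """

    name: str
    degree: int = 3


@dataclass(frozen=True)
class Spline:
    """Cubic P-spline term: B-spline basis + second-order difference penalty."""

    name: str
    n_knots: int = 10
    degree: int = 3


@dataclass(frozen=True)
class Categorical:
    """Dummy coding (drop first level) of a categorical column."""

    name: str


@dataclass(frozen=True)
class Interaction:
    """Product of two numeric covariate columns."""

    left: str
    right: str


Term = Linear | Poly | Spline | Categorical | Interaction


def _diff_matrix(n: int, order: int = 2) -> np.ndarray:
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d


@dataclass
class _EncodedTerm:
    term: Term
    columns: list[str]
    # term-specific state needed at transform time
    state: dict = field(default_factory=dict)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        t = self.term
        if isinstance(t, Linear):
            return np.asarray(df[t.name], dtype=float)[:, None]
        if isinstance(t, Interaction):
            return (
                np.asarray(df[t.left], dtype=float)
                * np.asarray(df[t.right], dtype=float)
            )[:, None]
        if isinstance(t, Poly):
            x = np.asarray(df[t.name], dtype=float)
            z = (x - self.state["center"]) / self.state["scale"]
            return np.column_stack([z**d for d in range(1, t.degree + 1)])
        if isinstance(t, Categorical):
            x = np.asarray(df[t.name])
            levels = self.state["levels"]
            out = np.zeros((len(x), len(levels) - 1))
            for j, lev in enumerate(levels[1:]):
                out[:, j] = x == lev
            return out
        if isinstance(t, Spline):
            x = np.asarray(df[t.name], dtype=float)
            lo, hi = self.state["bounds"]
            if np.any(x < lo) or np.any(x > hi):
                warnings.warn(
                    f"spline term '{t.name}': values outside the training range "
                    "are clipped to the boundary knots",
                    stacklevel=2,
                )
                x = np.clip(x, lo, hi)
            knots = self.state["knots"]
            basis = BSpline.design_matrix(x, knots, t.degree).toarray()
            basis = basis[:, 1:] - self.state["col_means"]
            return basis
        raise TypeError(f"unknown term type: {t!r}")


@dataclass
class DesignInfo:
    """Fitted design: rebuilds the matrix on new data and exposes the penalty."""

    terms: list[Term]
    encoded: list[_EncodedTerm]
    column_names: list[str]
    include_intercept: bool
    penalty_blocks: list[tuple[slice, np.ndarray]]

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        parts: list[np.ndarray] = []
        if self.include_intercept:
            parts.append(np.ones((n, 1)))
        for enc in self.encoded:
            parts.append(enc.transform(df))
        if not parts:
            return np.empty((n, 0))
        return np.hstack(parts)

    def penalty(self) -> np.ndarray:
        """Full-size penalty matrix (zero outside spline blocks)."""
        p = np.zeros((self.n_columns, self.n_columns))
        for sl, pen in self.penalty_blocks:
            p[sl, sl] = pen
        return p

    # -- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        encs = []
        for enc in self.encoded:
            t = enc.term
            state = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in enc.state.items()
            }
            encs.append(
                {
                    "type": type(t).__name__,
                    "term": t.__dict__,
                    "columns": enc.columns,
                    "state": state,
                }
            )
        return {
            "include_intercept": self.include_intercept,
            "encoded": encs,
            "column_names": self.column_names,
            "penalty_blocks": [
                [sl.start, sl.stop, pen.tolist()] for sl, pen in self.penalty_blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignInfo":
        term_types = {
            "Linear": Linear,
            "Poly": Poly,
            "Spline": Spline,
            "Categorical": Categorical,
            "Interaction": Interaction,
        }
        encoded = []
        for e in d["encoded"]:
            term = term_types[e["type"]](**e["term"])
            state = {
                k: (np.asarray(v) if isinstance(v, list) else v)
                for k, v in e["state"].items()
            }
            if "levels" in state:
                state["levels"] = list(state["levels"])
            encoded.append(_EncodedTerm(term, e["columns"], state))
        blocks = [
            (slice(a, b), np.asarray(p)) for a, b, p in d["penalty_blocks"]
        ]
        return cls(
            terms=[e.term for e in encoded],
            encoded=encoded,
            column_names=d["column_names"],
            include_intercept=d["include_intercept"],
            penalty_blocks=blocks,
        )


def build_design(
    df: pd.DataFrame,
    terms: Sequence[Term],
    include_intercept: bool = True,
) -> tuple[np.ndarray, DesignInfo]:
    """Build a design matrix and the fitted :class:`DesignInfo` from data.

    Raises ``ValueError`` for missing columns, non-finite covariates, spline
    terms with too few distinct values, or a rank-deficient design (naming
    the aliased columns).
    """
    encoded: list[_EncodedTerm] = []
    names: list[str] = []
    blocks: list[tuple[slice, np.ndarray]] = []
    offset = 1 if include_intercept else 0
    if include_intercept:
        names.append("intercept")

    for t in terms:
        cols_needed = (
            [t.left, t.right] if isinstance(t, Interaction) else [t.name]
        )
        for c in cols_needed:
            if c not in df.columns:
                raise ValueError(f"covariate column '{c}' not found")
        if isinstance(t, Linear):
            x = np.asarray(df[t.name], dtype=float)
            _check_finite(x, t.name)
            enc = _EncodedTerm(t, [t.name])
        elif isinstance(t, Interaction):
            enc = _EncodedTerm(t, [f"{t.left}:{t.right}"])
        elif isinstance(t, Poly):
            x = np.asarray(df[t.name], dtype=float)
            _check_finite(x, t.name)
            scale = float(np.std(x))
            if scale == 0:
                raise ValueError(f"polynomial term '{t.name}': covariate is constant")
            enc = _EncodedTerm(
                t,
                [f"{t.name}^{d}" for d in range(1, t.degree + 1)],
                {"center": float(np.mean(x)), "scale": scale},
            )
        elif isinstance(t, Categorical):
            levels = sorted(pd.unique(np.asarray(df[t.name])).tolist())
            if len(levels) < 2:
                raise ValueError(f"categorical term '{t.name}': fewer than 2 levels")
            enc = _EncodedTerm(
                t,
                [f"{t.name}[{lev}]" for lev in levels[1:]],
                {"levels": levels},
            )
        elif isinstance(t, Spline):
            x = np.asarray(df[t.name], dtype=float)
            _check_finite(x, t.name)
            if len(np.unique(x)) < t.n_knots:
                raise ValueError(
                    f"spline term '{t.name}': needs at least {t.n_knots} distinct "
                    f"values, got {len(np.unique(x))}"
                )
            lo, hi = float(np.min(x)), float(np.max(x))
            interior = np.linspace(lo, hi, t.n_knots + 2)[1:-1]
            knots = np.concatenate(
                [[lo] * (t.degree + 1), interior, [hi] * (t.degree + 1)]
            )
            basis = BSpline.design_matrix(x, knots, t.degree).toarray()
            col_means = basis[:, 1:].mean(axis=0)
            k_full = basis.shape[1]
            pen_full = _diff_matrix(k_full, 2)
            pen = (pen_full.T @ pen_full)[1:, 1:]
            n_cols = k_full - 1
            blocks.append((slice(offset, offset + n_cols), pen))
            enc = _EncodedTerm(
                t,
                [f"{t.name}_bs{j}" for j in range(n_cols)],
                {"knots": knots, "bounds": (lo, hi), "col_means": col_means},
            )
        else:
            raise TypeError(f"unknown term type: {t!r}")
        encoded.append(enc)
        names.extend(enc.columns)
        offset += len(enc.columns)

    info = DesignInfo(
        terms=list(terms),
        encoded=encoded,
        column_names=names,
        include_intercept=include_intercept,
        penalty_blocks=blocks,
    )
    x = info.transform(df)
    _check_rank(x, names, info)
    return x, info


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"covariate '{name}' contains non-finite values")


def _check_rank(x: np.ndarray, names: list[str], info: DesignInfo) -> None:
    if x.shape[1] == 0 or x.shape[0] == 0:
        return
    # penalized blocks may be deliberately rank-reduced; check with a whiff of
    # penalty so only genuinely aliased (data + penalty null space) columns trip
    gram = x.T @ x
    pen = info.penalty()
    norm = np.trace(gram) / max(x.shape[1], 1)
    a = gram + 1e-8 * norm * pen
    s = np.linalg.svd(a, compute_uv=False)
    if s[-1] > 1e-10 * s[0]:
        return
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    bad = piv[np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
    bad_names = [names[j] for j in bad] or [names[int(piv[-1])]]
    raise ValueError(f"design matrix is rank deficient; aliased columns: {bad_names}")


def penalized_lstsq_gcv(
    z: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray,
    lam_grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Penalized least squares with per-response GCV choice of one smoothing
    parameter shared across all penalty blocks.

    Parameters
    ----------
    z : (n, p) design; y : (n, k) responses; penalty : (p, p) PSD matrix.

    Returns
    -------
    coefs : (p, k), lam : (k,) chosen smoothing parameters, edf : (k,)
    effective degrees of freedom.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != z.shape[0]:
        y = y.T
    n, p = z.shape
    k = y.shape[1]
    ztz = z.T @ z
    zty = z.T @ y
    yty = np.einsum("ij,ij->j", y, y)

    if penalty.size == 0 or not np.any(penalty):
        coefs, *_ = np.linalg.lstsq(z, y, rcond=None)
        resid = y - z @ coefs
        edf = np.full(k, float(np.linalg.matrix_rank(z)))
        return coefs, np.zeros(k), edf

    if lam_grid is None:
        lam_grid = np.logspace(-4, 8, 25)
    lam_grid = np.asarray(lam_grid, dtype=float)
    scale = np.trace(ztz) / np.trace(penalty)

    gcv = np.full((len(lam_grid), k), np.inf)
    dfs = np.zeros(len(lam_grid))
    all_coefs = np.zeros((len(lam_grid), p, k))
    for i, lam in enumerate(lam_grid):
        a = ztz + lam * scale * penalty
        try:
            c = np.linalg.solve(a, zty)
            h = np.linalg.solve(a, ztz)
        except np.linalg.LinAlgError:
            continue
        df = float(np.trace(h))
        rss = yty - 2 * np.einsum("pk,pk->k", c, zty) + np.einsum(
            "pk,pq,qk->k", c, ztz, c
        )
        rss = np.maximum(rss, 0.0)
        gcv[i] = n * rss / max(n - df, 1e-8) ** 2
        dfs[i] = df
        all_coefs[i] = c
    best = np.argmin(gcv, axis=0)
    coefs = np.stack([all_coefs[best[j], :, j] for j in range(k)], axis=1)
    lam = lam_grid[best] * scale
    edf = dfs[best]
    return coefs, lam, edf
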