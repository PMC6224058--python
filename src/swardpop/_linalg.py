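"""Sequential (Type-I) variance decomposition via nested orthonormal bases.

Terms are added in a fixed order; each term contributes the orthogonal
complement of its design columns relative to everything already fitted.  The
per-term sum of squares is the squared norm of the response projected onto
those new directions, so term SS plus residual SS equals the total SS (about
the mean) exactly, up to floating-point error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ValidationError
from .design import SampleDesign


def _orth_complement(X: np.ndarray, Q: np.ndarray, tol: float = 1e-8
                     ) -> np.ndarray:
    """Orthonormal basis of col(X) minus col(Q) (Q has orthonormal columns)."""
    R = X - Q @ (Q.T @ X)
    # double projection for numerical hygiene
    R -= Q @ (Q.T @ R)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    scale = max(np.linalg.norm(X), 1.0)
    return U[:, s > tol * scale]


def term_bases(
    blocks: list[tuple[str, np.ndarray]],
    n_obs: int,
    tol: float = 1e-8,
) -> list[tuple[str, np.ndarray]]:
    """Per-term orthonormal bases, after the intercept, in block order."""
    Q = np.full((n_obs, 1), 1.0 / np.sqrt(n_obs))
    out = []
    for name, X in blocks:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != n_obs:
            X = X.T
        if X.shape[0] != n_obs:
            raise ValidationError(f"block {name}: wrong number of rows")
        Qi = _orth_complement(X, Q, tol)
        out.append((name, Qi))
        if Qi.shape[1]:
            Q = np.hstack([Q, Qi])
    return out


def sequential_decomposition(
    Y: np.ndarray,
    blocks: list[tuple[str, np.ndarray]],
) -> pd.DataFrame:
    """Sequential SS of each block for every response column of Y.

    Y is n_obs x n_responses (a single response may be 1-D).  Returns a frame
    with one row per response and columns ``ss_<name>``, ``rss``, ``tss`` and
    attrs ``df`` (per-term df mapping, residual included).
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    bases = term_bases(blocks, n)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc**2).sum(axis=0)
    data = {}
    df: dict[str, int] = {}
    model_df = 0
    acc = np.zeros(Y.shape[1])
    for name, Qi in bases:
        proj = Qi.T @ Y
        ss = (proj**2).sum(axis=0)
        data[f"ss_{name}"] = ss
        df[name] = Qi.shape[1]
        model_df += Qi.shape[1]
        acc += ss
    data["rss"] = tss - acc
    data["tss"] = tss
    out = pd.DataFrame(data)
    # guard tiny negatives from cancellation
    out["rss"] = out["rss"].clip(lower=0.0)
    df["residual"] = n - 1 - model_df
    out.attrs["df"] = df
    return out


def design_blocks(
    design: list[SampleDesign],
    pc1: np.ndarray | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Model blocks in the paper's term order.

    Seed composition S, composition-by-replicate S:R, composition-by-year S:Y;
    an optional PC1 covariate is entered first.
    """
    comp = np.array([s.seed_composition for s in design])
    rep = np.array([s.replicate for s in design])
    year = np.array([s.year for s in design])

    def dummies(labels: np.ndarray) -> np.ndarray:
        levels = sorted(set(labels.tolist()))
        return (labels[:, None] == np.array(levels)[None, :]).astype(float)

    cells_sr = np.char.add(comp.astype(str), rep.astype(str))
    cells_sy = np.char.add(comp.astype(str), year.astype(str))
    blocks: list[tuple[str, np.ndarray]] = []
    if pc1 is not None:
        blocks.append(("pc1", np.asarray(pc1, float)[:, None]))
    blocks.append(("comp", dummies(comp)))
    blocks.append(("comp_rep", dummies(cells_sr)))
    blocks.append(("comp_year", dummies(cells_sy)))
    return blocks
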