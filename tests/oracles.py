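"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the shell oracle uses
explicit nearest-neighbour distances instead of a distance transform, and
the ANOVA oracle builds projection matrices from hand-coded sum-to-zero
design matrices instead of a formula interface.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import f as f_dist


def brute_force_shell(mask: np.ndarray, voxel_um: float, depth_um: float) -> np.ndarray:
    """Shell voxels by exact per-voxel distance to the border-connected background."""
    mask = np.asarray(mask, bool)
    labels, _ = ndimage.label(~mask)
    border = set()
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border.update(np.unique(labels[tuple(sl)]).tolist())
    border.discard(0)
    exterior = np.isin(labels, sorted(border))
    ext_pts = np.argwhere(exterior).astype(float)
    mask_pts = np.argwhere(mask).astype(float)
    shell = np.zeros_like(mask)
    if ext_pts.size == 0 or mask_pts.size == 0:
        return shell
    dist, _ = cKDTree(ext_pts).query(mask_pts)
    inside = dist * voxel_um <= depth_um + 1e-9
    shell[tuple(mask_pts[inside].astype(int).T)] = True
    return shell


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(values.unique(), key=str)
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    for i, lev in enumerate(levels[:-1]):
        cols[:, i] = (values == lev).astype(float)
    cols[(values == levels[-1]).to_numpy()] = -1.0
    return cols, levels


def _proj(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def anova_type3_oracle(
    table: pd.DataFrame, factor_a: str, factor_b: str, response: str
) -> dict:
    """Type III two-way ANOVA via explicit projection matrices.

    SS(effect) = SSE(model without the effect's columns) - SSE(full model),
    with sum-to-zero contrasts throughout.
    """
    y = table[response].to_numpy(dtype=float)
    n = y.size
    A, a_levels = _sum_code(table[factor_a])
    B, b_levels = _sum_code(table[factor_b])
    AB = np.concatenate(
        [A[:, [i]] * B[:, [j]] for i in range(A.shape[1]) for j in range(B.shape[1])],
        axis=1,
    )
    ones = np.ones((n, 1))
    blocks = {"a": A, "b": B, "ab": AB}

    def sse(parts):
        X = np.concatenate([ones] + parts, axis=1)
        resid = y - _proj(X) @ y
        return float(resid @ resid)

    sse_full = sse([A, B, AB])
    df_resid = n - (1 + A.shape[1] + B.shape[1] + AB.shape[1])
    out = {"sse": sse_full, "df_resid": df_resid}
    dfs = {"a": A.shape[1], "b": B.shape[1], "ab": AB.shape[1]}
    for name in ("a", "b", "ab"):
        others = [blocks[k] for k in ("a", "b", "ab") if k != name]
        ss = sse(others) - sse_full
        df = dfs[name]
        if df_resid > 0 and sse_full > 1e-12:
            F = (ss / df) / (sse_full / df_resid)
            p = float(f_dist.sf(F, df, df_resid))
        else:
            F, p = np.nan, np.nan
        out[name] = {"ss": max(ss, 0.0), "df": df, "F": F, "p": p}
    return out


def random_blob_mask(rng: np.random.Generator, side: int = 24) -> np.ndarray:
    """A random connected-ish blob inside a border of background."""
    field = ndimage.gaussian_filter(rng.normal(size=(side,) * 3), sigma=3.0)
    mask = field > np.quantile(field, 0.8)
    mask[[0, -1], :, :] = False
    mask[:, [0, -1], :] = False
    mask[:, :, [0, -1]] = False
    return mask
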