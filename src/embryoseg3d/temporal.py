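"""Bi-directional temporal prediction over nucleus tables.

Between consecutive frames a nucleus moves little and barely changes size,
so detections at t-1 and t+1 can vouch for a nucleus the segmentation missed
at t, and a detection at t with no partner in either neighbouring frame is a
transient artefact.  Both decisions use one dissimilarity score

    DS(A, B) = d / (0.5 * (r_A + r_B)) + (V_max / V_min - 1) ** 1.5

(displacement normalized by the mean radius, plus a volume-change penalty);
DS below the threshold (default 1.5) means "same nucleus".  The volume term
uses the larger-over-smaller ratio so the score is symmetric; a multiplier
variant ((ratio - 1) * 1.5) is selectable for auditability of the corrupted
source formula.

All operations take and return nucleus tables (see :mod:`embryoseg3d.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NUCLEUS_COLUMNS


@dataclass
class DissimilarityParams:
    ds_threshold: float = 1.5
    volume_term_form: str = "power"  # "power" | "multiplier"

    def __post_init__(self) -> None:
        if self.ds_threshold <= 0:
            raise ValueError("ds_threshold must be positive")
        if self.volume_term_form not in {"power", "multiplier"}:
            raise ValueError(f"unknown volume_term_form {self.volume_term_form!r}")


def dissimilarity(a: pd.Series, b: pd.Series, params: DissimilarityParams | None = None) -> float:
    """Dissimilarity score between two nucleus rows (dimensionless)."""
    params = params or DissimilarityParams()
    if a.volume_um3 <= 0 or b.volume_um3 <= 0:
        raise ValueError("volumes must be positive")
    d = float(
        np.sqrt(
            (a.x_um - b.x_um) ** 2 + (a.y_um - b.y_um) ** 2 + (a.z_um - b.z_um) ** 2
        )
    )
    shift = d / (0.5 * (a.radius_um + b.radius_um))
    ratio = max(a.volume_um3, b.volume_um3) / min(a.volume_um3, b.volume_um3)
    if params.volume_term_form == "power":
        vol_term = (ratio - 1.0) ** 1.5
    else:
        vol_term = (ratio - 1.0) * 1.5
    return shift + vol_term


def ds_matrix(a: pd.DataFrame, b: pd.DataFrame, params: DissimilarityParams) -> np.ndarray:
    """Pairwise dissimilarity matrix between two nucleus tables."""
    if len(a) == 0 or len(b) == 0:
        return np.empty((len(a), len(b)))
    if (a["volume_um3"] <= 0).any() or (b["volume_um3"] <= 0).any():
        raise ValueError("volumes must be positive")
    pa = a[["x_um", "y_um", "z_um"]].to_numpy()[:, None, :]
    pb = b[["x_um", "y_um", "z_um"]].to_numpy()[None, :, :]
    d = np.linalg.norm(pa - pb, axis=2)
    ra = a["radius_um"].to_numpy()[:, None]
    rb = b["radius_um"].to_numpy()[None, :]
    shift = d / (0.5 * (ra + rb))
    va = a["volume_um3"].to_numpy()[:, None]
    vb = b["volume_um3"].to_numpy()[None, :]
    ratio = np.maximum(va, vb) / np.minimum(va, vb)
    if params.volume_term_form == "power":
        vol_term = (ratio - 1.0) ** 1.5
    else:
        vol_term = (ratio - 1.0) * 1.5
    return shift + vol_term


def predict_missing(
    prev: pd.DataFrame,
    cur: pd.DataFrame,
    nxt: pd.DataFrame,
    params: DissimilarityParams | None = None,
) -> pd.DataFrame:
    """Fill single-frame gaps at the middle frame.

    For each (P in prev, N in next) pair with DS(P, N) below threshold where
    neither P nor N has any DS-below-threshold partner in ``cur``, insert a
    predicted nucleus at the midpoint with averaged radius/volume/gray.
    Pairing is greedy by ascending DS, one-to-one.
    """
    params = params or DissimilarityParams()
    thr = params.ds_threshold
    ds_pc = ds_matrix(prev, cur, params)
    ds_cn = ds_matrix(cur, nxt, params)
    ds_pn = ds_matrix(prev, nxt, params)
    p_matched = (
        (ds_pc < thr).any(axis=1) if ds_pc.size else np.zeros(len(prev), dtype=bool)
    )
    n_matched = (
        (ds_cn < thr).any(axis=0) if ds_cn.size else np.zeros(len(nxt), dtype=bool)
    )
    candidates = []
    for i in range(len(prev)):
        if p_matched[i]:
            continue
        for j in range(len(nxt)):
            if n_matched[j]:
                continue
            if ds_pn.size and ds_pn[i, j] < thr:
                candidates.append((ds_pn[i, j], i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_n: set[int] = set()
    new_rows = []
    all_ids = pd.concat([prev["nucleus_id"], cur["nucleus_id"], nxt["nucleus_id"]])
    next_id = int(all_ids.max()) + 1 if len(all_ids) else 1
    t_cur = int(cur["t"].iloc[0]) if len(cur) else (int(prev["t"].iloc[0]) + 1 if len(prev) else 0)
    for _, i, j in candidates:
        if i in used_p or j in used_n:
            continue
        used_p.add(i)
        used_n.add(j)
        p, n = prev.iloc[i], nxt.iloc[j]
        new_rows.append(
            {
                "nucleus_id": next_id,
                "t": t_cur,
                "x_um": 0.5 * (p.x_um + n.x_um),
                "y_um": 0.5 * (p.y_um + n.y_um),
                "z_um": 0.5 * (p.z_um + n.z_um),
                "radius_um": 0.5 * (p.radius_um + n.radius_um),
                "volume_um3": 0.5 * (p.volume_um3 + n.volume_um3),
                "mean_gray": 0.5 * (p.mean_gray + n.mean_gray),
                "n_slices": int(max(1, round(0.5 * (p.n_slices + n.n_slices)))),
                "provenance": "predicted",
            }
        )
        next_id += 1
    if not new_rows:
        return cur.copy()
    return pd.concat([cur, pd.DataFrame(new_rows, columns=NUCLEUS_COLUMNS)], ignore_index=True)


def flag_single_frame(
    prev: pd.DataFrame | None,
    cur: pd.DataFrame,
    nxt: pd.DataFrame | None,
    params: DissimilarityParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove nuclei at t with no DS partner at t-1 nor at t+1.

    Returns ``(kept, transients)``.  At the series boundary (``prev`` or
    ``nxt`` is None) the evidence is one-sided and nothing is flagged.
    """
    params = params or DissimilarityParams()
    if prev is None or nxt is None or len(cur) == 0:
        return cur.copy(), cur.iloc[0:0].copy()
    thr = params.ds_threshold
    ds_pc = ds_matrix(prev, cur, params)
    ds_cn = ds_matrix(cur, nxt, params)
    has_prev = (ds_pc < thr).any(axis=0) if ds_pc.size else np.zeros(len(cur), dtype=bool)
    has_next = (ds_cn < thr).any(axis=1) if ds_cn.size else np.zeros(len(cur), dtype=bool)
    transient = ~(has_prev | has_next)
    return cur.loc[~transient].reset_index(drop=True), cur.loc[transient].reset_index(drop=True)
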