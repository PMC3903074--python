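"""Detection scoring against ground truth: four-way error taxonomy.

Detections are matched one-to-one to ground-truth nuclei (greedy by
ascending center distance; a pair is admissible when the distance is below
the truth radius).  Every truth and every detection is then accounted for
exactly once:

* unmatched truth      -> false negative (FN)
* unmatched detection  -> false positive (FP)
* matched, relative radius error above tolerance -> false diameter (FD)
* matched, center offset above tolerance          -> dislocation (DL)
* matched otherwise    -> clean true positive

``true_positives`` counts all matched truths (so TP + FN equals the truth
count); FD and DL are sub-categories of matched pairs, FD taking precedence.
The accuracy rate is 1 - (FP + FN + FD + DL) / truth count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ErrorTolerances:
    """FD/DL tolerances (qualitative in the source taxonomy; explicit here).

    ``diameter_rel``: max relative radius error before a match counts as a
    false diameter.  Dislocation tolerance is ``dislocation_frac * truth
    radius`` unless an absolute ``dislocation_um`` is given.
    """

    diameter_rel: float = 0.5
    dislocation_frac: float = 0.5
    dislocation_um: float | None = None


@dataclass
class ErrorReport:
    per_frame: pd.DataFrame  # t, n_truth, tp, fp, fn, false_diameters, dislocations, accuracy_rate
    tolerances: ErrorTolerances

    def total(self, column: str) -> int:
        return int(self.per_frame[column].sum())

    @property
    def accuracy_rate(self) -> float:
        n_truth = self.per_frame["n_truth"].sum()
        if n_truth == 0:
            return 1.0
        errors = sum(
            self.per_frame[c].sum()
            for c in ("fp", "fn", "false_diameters", "dislocations")
        )
        return float(1.0 - errors / n_truth)

    def summary(self) -> str:
        lines = [
            "frame  truth  TP  FP  FN  FD  DL  accuracy",
        ]
        for row in self.per_frame.itertuples(index=False):
            lines.append(
                f"{row.t:>5}  {row.n_truth:>5}  {row.tp:>2}  {row.fp:>2}  {row.fn:>2}"
                f"  {row.false_diameters:>2}  {row.dislocations:>2}  {row.accuracy_rate:.3f}"
            )
        lines.append(f"overall accuracy rate: {self.accuracy_rate:.4f}")
        return "\n".join(lines)


def match_detections(
    detections: pd.DataFrame, truth: pd.DataFrame, t: int
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching at frame ``t``.

    Returns (detection index, truth index, distance) triples, using the
    positional indices of the frame-t sub-tables.  A pair is admissible when
    the center distance is below the truth radius.
    """
    det = detections[detections["t"] == t].reset_index(drop=True)
    tru = truth[truth["t"] == t].reset_index(drop=True)
    if len(det) == 0 or len(tru) == 0:
        return []
    pd_ = det[["x_um", "y_um", "z_um"]].to_numpy()[:, None, :]
    pt = tru[["x_um", "y_um", "z_um"]].to_numpy()[None, :, :]
    dist = np.linalg.norm(pd_ - pt, axis=2)
    admissible = dist < tru["radius_um"].to_numpy()[None, :]
    pairs = sorted(
        (dist[i, j], i, j)
        for i in range(len(det))
        for j in range(len(tru))
        if admissible[i, j]
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        out.append((i, j, float(d)))
    return out


def classify_errors(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    t: int,
    tolerances: ErrorTolerances | None = None,
) -> dict:
    """Error counts for one frame."""
    tol = tolerances or ErrorTolerances()
    det = detections[detections["t"] == t].reset_index(drop=True)
    tru = truth[truth["t"] == t].reset_index(drop=True)
    matching = match_detections(detections, truth, t)
    fd = dl = 0
    for i, j, dist in matching:
        r_true = float(tru.loc[j, "radius_um"])
        r_det = float(det.loc[i, "radius_um"])
        dl_tol = tol.dislocation_um if tol.dislocation_um is not None else tol.dislocation_frac * r_true
        if abs(r_det - r_true) / r_true > tol.diameter_rel:
            fd += 1
        elif dist > dl_tol:
            dl += 1
    tp = len(matching)
    fn = len(tru) - tp
    fp = len(det) - tp
    n_truth = len(tru)
    acc = 1.0 - (fp + fn + fd + dl) / n_truth if n_truth else 1.0
    return {
        "t": t,
        "n_truth": n_truth,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "false_diameters": fd,
        "dislocations": dl,
        "accuracy_rate": acc,
    }


def evaluate_series(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    tolerances: ErrorTolerances | None = None,
) -> ErrorReport:
    """Per-frame and aggregate error report over all truth frames."""
    tol = tolerances or ErrorTolerances()
    frames = sorted(truth["t"].unique())
    rows = [classify_errors(detections, truth, int(t), tol) for t in frames]
    return ErrorReport(pd.DataFrame(rows), tol)
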