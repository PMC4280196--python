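"""SPXY calibration/prediction partitioning.

SPXY (sample set partitioning based on joint x-y distances) extends the
Kennard-Stone design to regression: pairwise Euclidean distances are
computed separately on the spectra (x) and on the response (y), each is
normalised by its maximum over all pairs, and their sum is the joint
distance.  Selection is then Kennard-Stone on the joint distance — seed
with the pair at maximal joint distance, then repeatedly add the sample
whose minimum joint distance to the already-selected set is largest —
until the calibration quota is filled; the remainder is the prediction
set.  The procedure is fully deterministic (ties break toward the lowest
sample index).

With ``per_organ=True`` (the default in the pipeline) the selection runs
independently inside each organ stratum, which reproduces exactly
proportional per-organ calibration counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .hypercube_io import SpectraTable

__all__ = ["SplitResult", "pairwise_joint_distances", "spxy_select", "spxy_split"]


@dataclass
class SplitResult:
    """Index partition of a spectra table into calibration and prediction."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    calibration_ids: np.ndarray
    prediction_ids: np.ndarray
    fraction: float
    per_organ_counts: dict = field(default_factory=dict)

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_idx)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_idx)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "fraction": self.fraction,
                "calibration_ids": [str(s) for s in self.calibration_ids],
                "prediction_ids": [str(s) for s in self.prediction_ids],
                "per_organ_counts": self.per_organ_counts,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path, table: SpectraTable) -> "SplitResult":
        with open(path) as fh:
            d = json.load(fh)
        pos = {str(s): i for i, s in enumerate(table.sample_ids)}
        cal = np.array([pos[s] for s in d["calibration_ids"]], dtype=int)
        pred = np.array([pos[s] for s in d["prediction_ids"]], dtype=int)
        return cls(cal, pred, np.asarray(d["calibration_ids"], dtype=object),
                   np.asarray(d["prediction_ids"], dtype=object),
                   d["fraction"], d.get("per_organ_counts", {}))


def pairwise_joint_distances(table: SpectraTable) -> np.ndarray:
    """n x n matrix of max-normalised joint x-y distances.

    Symmetric with zero diagonal; each term is scaled to [0, 1] so every
    entry lies in [0, 2].  A degenerate term (all spectra identical, or
    all responses identical) is set to zero with a warning.
    """
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least two samples for pairwise distances")
    dx = squareform(pdist(table.X, metric="euclidean"))
    dy = squareform(pdist(table.y[:, None], metric="euclidean"))
    out = np.zeros((n, n))
    for name, d in (("x", dx), ("y", dy)):
        dmax = d.max()
        if dmax == 0:
            warnings.warn(
                f"all pairwise {name}-distances are zero; the {name} term "
                "of the joint distance is dropped", stacklevel=2)
        else:
            out += d / dmax
    return out


def spxy_select(d: np.ndarray, n_select: int) -> list[int]:
    """Kennard-Stone selection order on a precomputed joint-distance matrix.

    Returns ``n_select`` row indices: the maximal-distance pair first, then
    iteratively the sample maximising the minimum distance to the selected
    set.  All ties break toward the lowest index.
    """
    n = d.shape[0]
    if not (2 <= n_select <= n):
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")
    # seed pair: maximal joint distance, lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    k = int(np.argmax(flat))          # argmax is first-occurrence: lowest (i, j)
    selected = [int(iu[0][k]), int(iu[1][k])]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    # running minimum distance from each unselected sample to the selected set
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_select:
        cand = np.where(remaining)[0]
        pick = int(cand[np.argmax(min_d[cand])])
        selected.append(pick)
        remaining[pick] = False
        min_d = np.minimum(min_d, d[pick])
    return selected


def _quota(fraction: float, n: int) -> int:
    # round-half-up so 0.75 * 120 -> 90 and ties go to calibration
    return int(np.floor(fraction * n + 0.5))


def spxy_split(table: SpectraTable, calibration_fraction: float = 0.75,
               per_organ: bool = True) -> SplitResult:
    """Split a spectra table into calibration and prediction sets by SPXY.

    ``calibration_fraction`` of each stratum (each organ when
    ``per_organ``, else the whole table) goes to calibration; the quota is
    round-half-up.  Deterministic: no randomness anywhere.
    """
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must be in (0, 1)")
    n = table.n_samples

    strata: list[tuple[str, np.ndarray]]
    if per_organ:
        organs = [str(o) for o in table.organs]
        seen = list(dict.fromkeys(organs))          # stable order of appearance
        strata = [(o, np.where(np.array(organs) == o)[0]) for o in seen]
    else:
        strata = [("all", np.arange(n))]

    cal_parts, per_organ_counts = [], {}
    for name, idx in strata:
        m = len(idx)
        quota = _quota(calibration_fraction, m)
        if m < 2 or quota < 2 or quota > m - 1:
            raise ValueError(
                f"stratum {name!r} too small for an SPXY split: {m} samples, "
                f"calibration quota {quota}"
            )
        sub = table.subset(idx)
        order = spxy_select(pairwise_joint_distances(sub), quota)
        cal_parts.append(idx[np.array(order)])
        per_organ_counts[name] = {"calibration": quota, "prediction": m - quota}

    cal = np.sort(np.concatenate(cal_parts))
    mask = np.zeros(n, dtype=bool)
    mask[cal] = True
    pred = np.where(~mask)[0]
    return SplitResult(
        calibration_idx=cal, prediction_idx=pred,
        calibration_ids=table.sample_ids[cal],
        prediction_ids=table.sample_ids[pred],
        fraction=calibration_fraction, per_organ_counts=per_organ_counts,
    )
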