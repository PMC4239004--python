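"""Evaluation of energy functions against native-decoy distance measures.

Two report scores are used throughout.  The Pearson correlation between
per-decoy energies and distances measures how well an energy mimics the
desired linear funnel over the whole ensemble.  The R-score compares the
single decoy the energy picks (lowest energy, s_E) with the best decoy by
distance (s_d):

    R = (<d> - d(s_E)) / (<d> - d(s_d)),   clamped below at -1,

where <d> is the ensemble mean distance.  R = 1 when the energy picks the
best decoy; 0 is the random expectation for outlier-free ensembles; the
clamp stops outliers from producing arbitrarily negative values.  Because
any distance measure can itself play the role of a pseudo-energy, the same
two scores compare distance measures with each other (in which case the
R-score need not be symmetric).

Degenerate inputs (zero variance) yield an undefined flag (None), never a
crash; aggregation excludes flagged records and reports the exclusion
count.  Aggregates use the mean absolute deviation (l1) rather than the
standard deviation, which puts less weight on outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from funnelpot.distances import ElasticConfig, measure, normalize_measure_name
from funnelpot.potentials import (PotentialParams, consensus_contact_map,
                                  energy_ppd, energy_ppe)
from funnelpot.structures import ChainModel, DecoyEnsemble


@dataclass
class EvalRecord:
    """Per-ensemble, per-measure evaluation of one energy function."""

    ensemble_id: str
    measure: str
    corr: float | None          # None = undefined (zero variance)
    r_score: float | None       # None = undefined (all distances equal)
    best_by_energy: str         # decoy id s_E
    best_by_distance: str       # decoy id s_d
    d_mean: float


def pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; None if either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors, n >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def r_score(E: Sequence[float], d: Sequence[float],
            lower: float = -1.0) -> float | None:
    """R-score of an energy E against a distance d over one ensemble.

    Argmin ties break to the first index; returns None when all distances
    are equal (denominator zero).  Depends on E only through its argmin, so
    it is invariant to strictly increasing transforms of E.
    """
    E = np.asarray(E, dtype=float)
    d = np.asarray(d, dtype=float)
    if E.shape != d.shape or E.size < 2:
        raise ValueError("r_score needs two equal-length vectors, n >= 2")
    if np.ptp(d) == 0:
        return None
    s_E = int(np.argmin(E))
    s_d = int(np.argmin(d))
    if s_E == s_d:
        return 1.0
    d_mean = float(d.mean())
    return max(lower, (d_mean - d[s_E]) / (d_mean - d[s_d]))


def decoy_energies(params: PotentialParams, mode: str,
                   e: DecoyEnsemble,
                   cfg: ElasticConfig = ElasticConfig(),
                   min_sep: int | None = None) -> np.ndarray:
    """Energy of every decoy under the trained potential (PPD or PPE)."""
    mode = mode.lower()
    ms = min_sep if min_sep is not None else params.metadata.get("min_sep", 3)
    if mode == "ppd":
        return np.array([energy_ppd(d, params, min_sep=ms) for d in e.decoys])
    if mode == "ppe":
        S = consensus_contact_map(e, threshold=cfg.contact_threshold,
                                  min_sep=ms).S
        return np.array([energy_ppe(d, params, S) for d in e.decoys])
    raise ValueError(f"mode must be 'ppd' or 'ppe', got {mode!r}")


def evaluate_energy(params: PotentialParams, mode: str, e: DecoyEnsemble,
                    measures: Sequence[str],
                    cfg: ElasticConfig = ElasticConfig(),
                    ensemble_id: str | None = None) -> list[EvalRecord]:
    """One EvalRecord per requested distance measure.

    Energies are computed once; distances per measure.  Similarity-based
    measures are always evaluated in their starred distance form.
    """
    E = decoy_energies(params, mode, e, cfg)
    eid = ensemble_id if ensemble_id is not None else e.native.id
    records = []
    for which in measures:
        name = normalize_measure_name(which)
        d = np.array([measure(e.native, dec, name, cfg) for dec in e.decoys])
        records.append(EvalRecord(
            ensemble_id=eid, measure=name,
            corr=pearson(E, d), r_score=r_score(E, d),
            best_by_energy=e.decoys[int(np.argmin(E))].id,
            best_by_distance=e.decoys[int(np.argmin(d))].id,
            d_mean=float(d.mean())))
    return records


DistArg = str | Callable[[ChainModel, ChainModel], float] | Sequence[float]


def _distance_values(e: DecoyEnsemble, d: DistArg,
                     cfg: ElasticConfig) -> np.ndarray:
    if isinstance(d, str):
        return np.array([measure(e.native, dec, d, cfg) for dec in e.decoys])
    if callable(d):
        return np.array([d(e.native, dec) for dec in e.decoys])
    vals = np.asarray(d, dtype=float)
    if vals.shape != (len(e.decoys),):
        raise ValueError("precomputed distances have wrong length")
    return vals


def compare_distances(e: DecoyEnsemble, d1: DistArg, d2: DistArg,
                      cfg: ElasticConfig = ElasticConfig(),
                      ) -> tuple[float | None, float | None, float | None]:
    """Compare two distance measures on one ensemble.

    Treating d2 as a pseudo-energy for d1 and vice versa, returns
    (corr, r12, r21) with r12 = r_score(E=d2, d=d1) and
    r21 = r_score(E=d1, d=d2).
    """
    if len(e.decoys) < 2:
        raise ValueError("compare_distances needs at least 2 decoys")
    v1 = _distance_values(e, d1, cfg)
    v2 = _distance_values(e, d2, cfg)
    return pearson(v1, v2), r_score(v2, v1), r_score(v1, v2)


def aggregate(records: Sequence[EvalRecord],
              group_by: str = "measure") -> pd.DataFrame:
    """Mean and mean-absolute-deviation summary per group.

    Groups records by the given attribute (default: distance measure) and
    reports, for corr and r_score separately, the count of defined values,
    the count of excluded undefined records, the mean, and the mean
    absolute deviation around the mean.
    """
    rows = []
    keys = sorted({getattr(r, group_by) for r in records})
    for key in keys:
        group = [r for r in records if getattr(r, group_by) == key]
        row: dict = {group_by: key, "n_records": len(group)}
        for attr in ("corr", "r_score"):
            vals = np.array([getattr(r, attr) for r in group
                             if getattr(r, attr) is not None])
            row[f"{attr}_n"] = vals.size
            row[f"{attr}_excluded"] = len(group) - vals.size
            if vals.size:
                mean = float(vals.mean())
                row[f"{attr}_mean"] = mean
                row[f"{attr}_mad"] = float(np.abs(vals - mean).mean())
            else:
                row[f"{attr}_mean"] = np.nan
                row[f"{attr}_mad"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
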