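"""Cubic B-spline residue pair potentials and the consensus contact map.

The pair potential assigns every unordered pair of amino-acid types its own
distance-dependent interaction, modeled as a uniform cubic B-spline with
compact support on [1 Å, 12 Å] and 8 degrees of freedom, so each interaction
decays smoothly to zero beyond 12 Å and is unconstrained ("modeled freely")
on [4 Å, 9 Å] where the basis forms a partition of unity.  With 210
unordered pairs of the 20 standard amino acids this gives 210 x 8 = 1680
parameters.

PPD sums the spline energy over all counted residue pairs of a single
model; PPE restricts the sum to the pairs of a consensus contact map
computed from a decoy ensemble, sculpting an artificial funnel towards the
ensemble consensus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from funnelpot.distances import (CONTACT_THRESHOLD, MIN_SEP, ContactMap,
                                 contact_map)
from funnelpot.structures import STANDARD_AA, ChainModel, DecoyEnsemble

N_AA = 20
N_PAIRS = 210
N_BASIS = 8
N_PARAMS = N_PAIRS * N_BASIS  # 1680

#: uniform knot vector: integer Å positions 1..12
KNOTS = np.arange(1.0, 13.0)
SUPPORT = (1.0, 12.0)
#: interval on which the 8 basis functions sum to exactly 1
FREE_REGION = (4.0, 9.0)

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}

#: all unordered amino-acid pairs, lexicographic: ('A','A'), ('A','C'), ...
PAIRS: list[tuple[str, str]] = [
    (STANDARD_AA[i], STANDARD_AA[j])
    for i in range(N_AA) for j in range(i, N_AA)
]


@dataclass(frozen=True)
class SplineBasis:
    """The fixed uniform cubic B-spline basis of the pair potentials."""

    degree: int = 3
    knots: np.ndarray = field(default_factory=lambda: KNOTS.copy())
    n_basis: int = N_BASIS


def pair_index(a: str, b: str) -> int:
    """Index of the unordered amino-acid pair {a, b} in 0..209.

    Symmetric and bijective onto 0..209; ordering is lexicographic over
    sorted one-letter code pairs, so ('A','A') -> 0, ('A','C') -> 1, ...
    """
    try:
        i, j = _AA_INDEX[a], _AA_INDEX[b]
    except KeyError as exc:
        raise ValueError(f"non-standard amino-acid code {exc.args[0]!r}") from exc
    if i > j:
        i, j = j, i
    # row offset of i in the upper triangle (incl. diagonal) plus column
    return i * N_AA - i * (i - 1) // 2 + (j - i)


def _cardinal_cubic(u: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline on [0, 4], zero elsewhere (C^2 everywhere)."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    m = (u >= 0) & (u < 1)
    out[m] = u[m] ** 3 / 6.0
    m = (u >= 1) & (u < 2)
    v = u[m]
    out[m] = (-3 * v ** 3 + 12 * v ** 2 - 12 * v + 4) / 6.0
    m = (u >= 2) & (u < 3)
    v = u[m]
    out[m] = (3 * v ** 3 - 24 * v ** 2 + 60 * v - 44) / 6.0
    m = (u >= 3) & (u <= 4)
    v = u[m]
    out[m] = (4 - v) ** 3 / 6.0
    return out


def basis_matrix(d: np.ndarray) -> np.ndarray:
    """Evaluate all 8 basis functions at distances ``d`` -> shape (len(d), 8).

    On the uniform knot vector 1..12 the p-th basis function is the cardinal
    cubic B-spline shifted to [1+p, 5+p] Å.  All entries are >= 0 and rows
    are identically zero for d <= 1 or d >= 12.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    u = d[:, None] - (1.0 + np.arange(N_BASIS))[None, :]
    return _cardinal_cubic(u)


def basis_eval(d: float) -> np.ndarray:
    """The 8-vector (B_0(d), ..., B_7(d)) at a single distance d >= 0."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return basis_matrix(np.array([d]))[0]


@dataclass
class PotentialParams:
    """The 210 x 8 spline coefficient table of a trained pair potential.

    ``theta[pair_index(a, b), p]`` multiplies the p-th basis function for
    residue pair type {a, b}.  ``metadata`` records how the table was
    trained (distance measure, beta, PPD/PPE mode, min_sep).
    """

    theta: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (N_PAIRS, N_BASIS):
            raise ValueError(
                f"theta must have shape ({N_PAIRS}, {N_BASIS}) "
                f"= {N_PARAMS} coefficients, got {theta.shape}")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta contains non-finite coefficients")
        self.theta = theta

    @property
    def flat(self) -> np.ndarray:
        """Coefficients as the length-1680 vector X, slot = pair*8 + p."""
        return self.theta.reshape(-1)

    @classmethod
    def zeros(cls, metadata: dict | None = None) -> "PotentialParams":
        return cls(np.zeros((N_PAIRS, N_BASIS)), metadata or {})

    # -- serialization (bit-exact round-trip via 17-significant-digit text) --

    def to_tsv(self, path: str) -> None:
        rows = [(a, b, p, repr(float(self.theta[idx, p])))
                for idx, (a, b) in enumerate(PAIRS) for p in range(N_BASIS)]
        df = pd.DataFrame(rows, columns=["aa1", "aa2", "p", "theta"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, metadata: dict | None = None) -> "PotentialParams":
        df = pd.read_csv(path, sep="\t", dtype={"aa1": str, "aa2": str},
                         float_precision="round_trip")
        if len(df) != N_PARAMS:
            raise ValueError(
                f"parameter table has {len(df)} rows, expected {N_PARAMS}")
        theta = np.full((N_PAIRS, N_BASIS), np.nan)
        for aa1, aa2, p, val in zip(df.aa1, df.aa2, df.p, df.theta):
            theta[pair_index(aa1, aa2), int(p)] = float(val)
        return cls(theta, metadata or {})

    def to_json(self, path: str) -> None:
        payload = {"metadata": self.metadata,
                   "theta": [[float(v) for v in row] for row in self.theta]}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "PotentialParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["theta"], dtype=float),
                   payload.get("metadata", {}))


def _counted_pairs(n: int, min_sep: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=min_sep)
    return i, j


def _pair_type_indices(seq: str, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    aa = np.array([_AA_INDEX[a] for a in seq])
    ii, jj = np.minimum(aa[i], aa[j]), np.maximum(aa[i], aa[j])
    return ii * N_AA - ii * (ii - 1) // 2 + (jj - ii)


def _pair_energy(m: ChainModel, theta: np.ndarray,
                 i: np.ndarray, j: np.ndarray) -> float:
    if i.size == 0:
        return 0.0
    d = np.linalg.norm(m.coords[i] - m.coords[j], axis=1)
    B = basis_matrix(d)
    ptype = _pair_type_indices(m.seq, i, j)
    return float(np.sum(theta[ptype] * B))


def energy_ppd(m: ChainModel, params: PotentialParams,
               min_sep: int = MIN_SEP) -> float:
    """PPD energy: spline pair energy summed over all counted residue pairs
    (|i-j| >= min_sep).  Depends only on internal distances, hence invariant
    under rigid motion."""
    i, j = _counted_pairs(len(m), min_sep)
    return _pair_energy(m, params.theta, i, j)


def energy_ppe(m: ChainModel, params: PotentialParams, S: ContactMap) -> float:
    """PPE energy: spline pair energy restricted to the pairs of the
    consensus contact map S.  Equals PPD when S is the full
    min_sep-filtered map."""
    if S.n != len(m):
        raise ValueError(f"consensus map size {S.n} != model length {len(m)}")
    i, j = S.pairs
    return _pair_energy(m, params.theta, i, j)


@dataclass
class ConsensusState:
    """Result of the iterative consensus contact-map computation.

    ``M`` holds the fraction of *selected* decoys having each contact at
    convergence; ``S`` the thresholded binary map; ``selected`` the ids of
    the decoys in the final 25% subset; ``iteration`` the number of
    refinement rounds performed.
    """

    M: np.ndarray
    S: ContactMap
    selected: list[str]
    iteration: int
    converged: bool = True


def consensus_contact_map(e: DecoyEnsemble, mu: float = 0.25,
                          keep: float = 0.25, max_iter: int = 20,
                          threshold: float = CONTACT_THRESHOLD,
                          min_sep: int = MIN_SEP) -> ConsensusState:
    """Iterative consensus contact map of a decoy ensemble.

    Starting from the full ensemble: (1) M_ij = fraction of currently
    selected decoys whose own contact map has contact (i, j); (2) threshold
    S = [M >= mu]; (3) re-select the ceil(keep * n) decoys of the *full*
    ensemble closest to S in upper-triangle Hamming distance (ties broken
    by decoy order).  Stops when S is unchanged or after ``max_iter``
    rounds; the procedure usually converges in a few steps.

    Ensembles with fewer than 8 decoys get a single-pass map (25% of so few
    decoys is degenerate).
    """
    n_dec = len(e.decoys)
    if n_dec == 0:
        raise ValueError("empty ensemble")
    n = e.n_res
    iu, ju = np.triu_indices(n, k=min_sep)
    maps = np.empty((n_dec, iu.size), dtype=bool)
    for k, d in enumerate(e.decoys):
        maps[k] = contact_map(d, threshold, min_sep).contacts[iu, ju]

    def to_state(sel: np.ndarray, flat_M: np.ndarray, flat_S: np.ndarray,
                 iteration: int, converged: bool = True) -> ConsensusState:
        M = np.zeros((n, n))
        M[iu, ju] = flat_M
        M = M + M.T
        Sm = np.zeros((n, n), dtype=bool)
        Sm[iu, ju] = flat_S
        Sm |= Sm.T
        S = ContactMap(n=n, contacts=Sm, threshold=threshold, min_sep=min_sep)
        return ConsensusState(M=M, S=S,
                              selected=[e.decoys[k].id for k in sel],
                              iteration=iteration, converged=converged)

    selected = np.arange(n_dec)
    flat_M = maps.mean(axis=0)
    flat_S = flat_M >= mu
    if n_dec < 8:
        return to_state(selected, flat_M, flat_S, iteration=1)

    n_keep = math.ceil(keep * n_dec)
    iteration = 0
    converged = False
    for iteration in range(1, max_iter + 1):
        hamming = np.count_nonzero(maps != flat_S[None, :], axis=1)
        selected = np.argsort(hamming, kind="stable")[:n_keep]
        selected.sort()
        flat_M = maps[selected].mean(axis=0)
        new_S = flat_M >= mu
        if np.array_equal(new_S, flat_S):
            converged = True
            break
        flat_S = new_S
    return to_state(selected, flat_M, flat_S, iteration=iteration,
                    converged=converged)
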