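"""Funnel-sculpting trainer for the spline pair potentials.

The trainer assumes the energy gap between a decoy and its native is
linearly related to a chosen native-decoy distance measure.  Because both
PPD and PPE are linear in the coefficient vector X, the per-decoy energy
gap is an inner product Delta E_ij = phi_ij . X with a precomputable
feature vector phi (decoy basis sums minus native basis sums).  Training
minimizes

    sum_ij (phi_ij . X - c_i d_ij)^2  +  beta ||X||^2

jointly over X and the per-protein proportionality constants c_i, subject
to c_i >= c_bound (default 1, which excludes the trivial X = 0 solution
and fixes the energy scale).  This is a convex bound-constrained linear
least-squares problem; we solve it with scipy's lsq_linear.  An
alternating-minimization solver using the closed-form c update is provided
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import lsq_linear

from funnelpot.distances import MIN_SEP, ContactMap, ElasticConfig, measure
from funnelpot.errors import DegenerateInputError, SolverError
from funnelpot.potentials import (N_BASIS, N_PARAMS, PotentialParams,
                                  _counted_pairs, _pair_type_indices,
                                  basis_matrix, consensus_contact_map)
from funnelpot.structures import ChainModel, DecoyEnsemble

DistanceSpec = str | Callable[[ChainModel, ChainModel], float]


@dataclass
class TrainingProblem:
    """Assembled QP inputs: feature gaps, target distances, grouping."""

    feature_gaps: np.ndarray          # (n_rows, 1680)
    dists: np.ndarray                 # (n_rows,)
    protein_index: np.ndarray         # (n_rows,) int, decoy row -> protein
    M: int                            # number of proteins
    beta: float
    c_bounds: np.ndarray              # (M,) lower bound for each c_i

    def __post_init__(self):
        self.feature_gaps = np.asarray(self.feature_gaps, dtype=float)
        self.dists = np.asarray(self.dists, dtype=float)
        self.protein_index = np.asarray(self.protein_index, dtype=int)
        self.c_bounds = np.asarray(self.c_bounds, dtype=float)
        n = self.feature_gaps.shape[0]
        if self.feature_gaps.ndim != 2 or self.feature_gaps.shape[1] != N_PARAMS:
            raise ValueError(f"feature rows must have {N_PARAMS} entries")
        if self.dists.shape != (n,) or self.protein_index.shape != (n,):
            raise ValueError("dists/protein_index length mismatch")
        if np.any(self.dists < 0):
            raise ValueError("target distances must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.c_bounds.shape != (self.M,):
            raise ValueError("c_bounds must have one entry per protein")


@dataclass
class FitResult:
    """Trained potential plus the per-protein proportionality constants."""

    params: PotentialParams
    c: np.ndarray
    objective: float
    solver_status: str


def _feature_vector(m: ChainModel, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Basis sums of one model accumulated into the (pair_type, p) slots."""
    phi = np.zeros((N_PARAMS // N_BASIS, N_BASIS))
    if i.size:
        d = np.linalg.norm(m.coords[i] - m.coords[j], axis=1)
        B = basis_matrix(d)
        ptype = _pair_type_indices(m.seq, i, j)
        np.add.at(phi, ptype, B)
    return phi.reshape(-1)


def featurize(e: DecoyEnsemble, mode: str = "ppd",
              d_measure: DistanceSpec | None = "rmsd",
              cfg: ElasticConfig = ElasticConfig(),
              min_sep: int = MIN_SEP,
              consensus: ContactMap | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-decoy feature gaps phi and target distances d for one ensemble.

    phi_j = (decoy basis sums) - (native basis sums); in PPE mode both sums
    are restricted to the consensus contact map (computed here if not
    supplied).  ``d_measure`` is a measure name or a callable
    (native, decoy) -> float; pass None to skip distance computation
    (targets supplied externally), in which case d is returned as zeros.
    """
    mode = mode.lower()
    if mode not in ("ppd", "ppe"):
        raise ValueError(f"mode must be 'ppd' or 'ppe', got {mode!r}")
    if mode == "ppe":
        S = consensus if consensus is not None else consensus_contact_map(
            e, threshold=cfg.contact_threshold, min_sep=min_sep).S
        i, j = S.pairs
    else:
        i, j = _counted_pairs(e.n_res, min_sep)

    phi_native = _feature_vector(e.native, i, j)
    Phi = np.empty((len(e.decoys), N_PARAMS))
    d = np.zeros(len(e.decoys))
    for row, decoy in enumerate(e.decoys):
        Phi[row] = _feature_vector(decoy, i, j) - phi_native
        if d_measure is not None:
            if callable(d_measure):
                d[row] = d_measure(e.native, decoy)
            else:
                d[row] = measure(e.native, decoy, d_measure, cfg)
    return Phi, d


def _objective(problem: TrainingProblem, x: np.ndarray, c: np.ndarray) -> float:
    resid = problem.feature_gaps @ x - c[problem.protein_index] * problem.dists
    return float(resid @ resid + problem.beta * (x @ x))


def _check_solvable(problem: TrainingProblem) -> None:
    if problem.feature_gaps.shape[0] == 0:
        raise DegenerateInputError("training problem has no rows")
    if np.all(problem.dists <= 1e-6):
        raise DegenerateInputError(
            "all target distances are (effectively) zero; the funnel slope "
            "is unidentifiable")


def solve(problem: TrainingProblem, tol: float = 1e-12,
          max_iter: int | None = None) -> FitResult:
    """Solve the joint QP over (X, c) with scipy's bounded least squares.

    Variables are stacked z = (X, c); data rows read phi.X - d_ij c_i and
    the ridge term contributes sqrt(beta) * I rows on X.  The problem is
    convex, so the optimum is solver-independent to tolerance.
    """
    _check_solvable(problem)
    n_rows = problem.feature_gaps.shape[0]
    M = problem.M

    D = sp.csr_matrix(
        (-problem.dists, (np.arange(n_rows), problem.protein_index)),
        shape=(n_rows, M))
    A_data = sp.hstack([sp.csr_matrix(problem.feature_gaps), D])
    blocks = [A_data]
    if problem.beta > 0:
        reg = sp.hstack([np.sqrt(problem.beta) * sp.eye(N_PARAMS),
                         sp.csr_matrix((N_PARAMS, M))])
        blocks.append(reg)
    A = sp.vstack(blocks, format="csr")
    b = np.zeros(A.shape[0])

    lb = np.concatenate([np.full(N_PARAMS, -np.inf), problem.c_bounds])
    ub = np.full(N_PARAMS + M, np.inf)
    res = lsq_linear(A, b, bounds=(lb, ub), tol=tol,
                     max_iter=max_iter, method="trf")
    if res.status <= 0:
        raise SolverError(f"lsq_linear did not converge: {res.message}",
                          solver_status=str(res.status))
    x, c = res.x[:N_PARAMS], res.x[N_PARAMS:]
    c = np.maximum(c, problem.c_bounds)  # guard round-off at active bounds
    params = PotentialParams(x.reshape(-1, N_BASIS))
    return FitResult(params=params, c=c,
                     objective=_objective(problem, x, c),
                     solver_status=f"lsq_linear/trf status {res.status}")


def optimal_c(problem: TrainingProblem, x: np.ndarray) -> np.ndarray:
    """Closed-form optimal c given X: per protein,
    max(c_bound, sum_j DeltaE_ij d_ij / sum_j d_ij^2)."""
    gaps = problem.feature_gaps @ x
    c = np.empty(problem.M)
    for i in range(problem.M):
        rows = problem.protein_index == i
        d = problem.dists[rows]
        denom = d @ d
        c[i] = (gaps[rows] @ d) / denom if denom > 0 else problem.c_bounds[i]
    return np.maximum(c, problem.c_bounds)


def solve_alternating(problem: TrainingProblem, n_iter: int = 50,
                      rtol: float = 1e-10) -> FitResult:
    """Alternating minimization over X (ridge solve) and c (closed form).

    Converges to the joint optimum because the objective is jointly convex
    and each block update is exact; used as an independent cross-check of
    :func:`solve`.
    """
    _check_solvable(problem)
    c = problem.c_bounds.copy()
    Phi = problem.feature_gaps
    if problem.beta > 0:
        A = np.vstack([Phi, np.sqrt(problem.beta) * np.eye(N_PARAMS)])
    else:
        A = Phi
    x = np.zeros(N_PARAMS)
    prev_obj = np.inf
    for _ in range(n_iter):
        y = c[problem.protein_index] * problem.dists
        rhs = np.concatenate([y, np.zeros(N_PARAMS)]) if problem.beta > 0 else y
        x = np.linalg.lstsq(A, rhs, rcond=None)[0]
        c = optimal_c(problem, x)
        obj = _objective(problem, x, c)
        if prev_obj - obj <= rtol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj
    return FitResult(params=PotentialParams(x.reshape(-1, N_BASIS)),
                     c=c, objective=_objective(problem, x, c),
                     solver_status="alternating")


def assemble_problem(ensembles: Sequence[DecoyEnsemble], mode: str = "ppd",
                     d_measure: DistanceSpec | None = "rmsd",
                     beta: float | None = None,
                     cfg: ElasticConfig = ElasticConfig(),
                     min_sep: int = MIN_SEP,
                     c_bound: float = 1.0,
                     targets: Sequence[np.ndarray] | None = None,
                     ) -> TrainingProblem:
    """Featurize all ensembles and stack them into one TrainingProblem.

    ``targets`` optionally supplies precomputed per-ensemble target
    distances (e.g. planted funnels), overriding ``d_measure``.  Default
    beta is 1e-3 times the number of rows.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if targets is not None and len(targets) != len(ensembles):
        raise ValueError("targets must have one array per ensemble")
    Phis, ds, pidx = [], [], []
    for i, e in enumerate(ensembles):
        Phi, d = featurize(e, mode=mode,
                           d_measure=None if targets is not None else d_measure,
                           cfg=cfg, min_sep=min_sep)
        if targets is not None:
            d = np.asarray(targets[i], dtype=float)
            if d.shape != (len(e.decoys),):
                raise ValueError(f"targets[{i}] has wrong length")
        Phis.append(Phi)
        ds.append(d)
        pidx.append(np.full(len(e.decoys), i))
    n_rows = sum(len(d) for d in ds)
    if beta is None:
        beta = 1e-3 * n_rows
    return TrainingProblem(
        feature_gaps=np.vstack(Phis), dists=np.concatenate(ds),
        protein_index=np.concatenate(pidx), M=len(ensembles),
        beta=beta, c_bounds=np.full(len(ensembles), c_bound))


def fit_potential(ensembles: Sequence[DecoyEnsemble], mode: str = "ppd",
                  d_measure: DistanceSpec | None = "rmsd",
                  beta: float | None = None,
                  cfg: ElasticConfig = ElasticConfig(),
                  min_sep: int = MIN_SEP, c_bound: float = 1.0,
                  targets: Sequence[np.ndarray] | None = None) -> FitResult:
    """End-to-end trainer: featurize, assemble the QP, solve.

    The returned parameter table carries training metadata (mode, measure,
    beta, min_sep).
    """
    problem = assemble_problem(ensembles, mode=mode, d_measure=d_measure,
                               beta=beta, cfg=cfg, min_sep=min_sep,
                               c_bound=c_bound, targets=targets)
    result = solve(problem)
    result.params.metadata.update({
        "mode": mode.lower(),
        "distance": ("precomputed" if targets is not None
                     else getattr(d_measure, "__name__", str(d_measure))),
        "beta": problem.beta,
        "min_sep": min_sep,
        "c_bound": c_bound,
        "n_proteins": problem.M,
        "n_rows": int(problem.feature_gaps.shape[0]),
    })
    return result
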