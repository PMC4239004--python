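"""Synthetic decoy ensembles with controlled geometry and planted funnels.

Real decoy collections come from conformational-sampling programs; this
module emulates their essential features so the whole pipeline is testable
without external data.  A native is a compact self-avoiding random Cα walk
(fixed 3.8 Å virtual bonds, clash floor, radius-of-gyration acceptance
bound to keep chains globular — overly extended chains carry almost no
contacts and are easily overfitted).  Decoys perturb the native with
chain-smoothed Gaussian noise at a grid of amplitudes followed by a random
rigid motion, so extrinsic measures (RMSD, GDT-TS*) and intrinsic ones
(Q*, MT) diverge realistically.  A planted linear energy-distance funnel
(targets d = phi . theta*) provides ground truth for trainer-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from funnelpot.errors import GenerationError
from funnelpot.structures import STANDARD_AA, ChainModel, DecoyEnsemble

#: floor applied to planted target distances (must stay nonnegative)
PLANTED_EPS = 1e-6


@dataclass
class SynthConfig:
    """Knobs of the synthetic generator.

    noise_grid lists per-coordinate Gaussian sigmas (Å); the decoy budget
    is split evenly across the grid.  bond_length is the Cα-Cα virtual
    bond (3.8 Å); min_clash the smallest allowed non-adjacent Cα-Cα
    distance.  sequence_mode is "random" or a fixed one-letter sequence.
    """

    n_res: int = 40
    n_decoys: int = 100
    noise_grid: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    bond_length: float = 3.8
    min_clash: float = 4.0
    seed: int = 0
    sequence_mode: str = "random"
    compact_pull: float = 0.6        # strength of the centroid bias
    rg_factor: float = 3.0           # accept chains with Rg <= factor * N^(1/3)
    max_restarts: int = 200

    def __post_init__(self):
        if self.n_res < 5:
            raise ValueError("n_res must be >= 5")
        if any(s < 0 for s in self.noise_grid):
            raise ValueError("noise sigmas must be >= 0")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")


def _rng(cfg_seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_chain(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray | None:
    coords = np.zeros((cfg.n_res, 3))
    coords[1] = [cfg.bond_length, 0.0, 0.0]
    for i in range(2, cfg.n_res):
        centroid = coords[:i].mean(axis=0)
        placed = False
        for _ in range(60):
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            direction = _random_unit(rng)
            if norm > 1e-9:
                direction = direction + cfg.compact_pull * pull / norm
                direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + cfg.bond_length * direction
            # self-avoidance: keep non-adjacent residues outside min_clash
            if i >= 2:
                dmin = cdist(candidate[None, :], coords[:i - 1]).min()
                if dmin < cfg.min_clash:
                    continue
            coords[i] = candidate
            placed = True
            break
        if not placed:
            return None
    return coords


def gen_native(cfg: SynthConfig,
               rng: np.random.Generator | None = None) -> ChainModel:
    """Compact self-avoiding random Cα walk with a random sequence.

    Consecutive Cα distances equal bond_length exactly; non-adjacent pairs
    stay >= min_clash; chains are regrown until the radius of gyration is
    below rg_factor * n_res^(1/3) Å (globularity).  Deterministic for a
    fixed seed.
    """
    if rng is None:
        rng = _rng(cfg.seed, stream=0)
    rg_bound = cfg.rg_factor * cfg.n_res ** (1.0 / 3.0)
    coords = None
    for _ in range(cfg.max_restarts):
        trial = _grow_chain(cfg, rng)
        if trial is None:
            continue
        rg = np.sqrt(np.mean(np.sum((trial - trial.mean(axis=0)) ** 2, axis=1)))
        if rg <= rg_bound:
            coords = trial
            break
    if coords is None:
        raise GenerationError(
            "could not grow a compact self-avoiding chain; relax min_clash "
            "or rg_factor")
    if cfg.sequence_mode == "random":
        seq = "".join(rng.choice(list(STANDARD_AA), size=cfg.n_res))
    else:
        seq = cfg.sequence_mode
        if len(seq) != cfg.n_res:
            raise ValueError("fixed sequence length != n_res")
    return ChainModel(id=f"native_s{cfg.seed}", seq=seq, coords=coords,
                      backbone_complete=np.ones(cfg.n_res, dtype=bool))


def _smooth_noise(noise: np.ndarray) -> np.ndarray:
    """Window-3 moving average along the chain (reflected ends).

    Smoothing correlates neighbouring displacements, which roughly
    preserves virtual bond lengths while still deforming the global fold.
    """
    padded = np.vstack([noise[:1], noise, noise[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _random_rigid(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    quat = rng.normal(size=4)
    R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return coords @ R.T + t


def gen_decoys(native: ChainModel, cfg: SynthConfig,
               rng: np.random.Generator | None = None,
               provenance: str = "synthetic") -> DecoyEnsemble:
    """Decoys = native + chain-smoothed Gaussian noise + random rigid motion.

    The decoy budget is split evenly over noise_grid (earlier sigmas absorb
    any remainder).  sigma = 0 decoys differ from the native by a rigid
    motion only, so every distance measure returns 0 for them.
    """
    if rng is None:
        rng = _rng(cfg.seed, stream=1)
    n_grid = len(cfg.noise_grid)
    base, extra = divmod(cfg.n_decoys, n_grid)
    decoys: list[ChainModel] = []
    for g, sigma in enumerate(cfg.noise_grid):
        count = base + (1 if g < extra else 0)
        for _ in range(count):
            noise = rng.normal(scale=sigma, size=native.coords.shape) \
                if sigma > 0 else np.zeros_like(native.coords)
            coords = native.coords + _smooth_noise(noise)
            coords = _random_rigid(rng, coords)
            decoys.append(ChainModel(
                id=f"decoy_{len(decoys):04d}_sig{sigma:g}",
                seq=native.seq, coords=coords,
                backbone_complete=np.ones(len(native), dtype=bool)))
    return DecoyEnsemble(native=native, decoys=decoys, provenance=provenance)


def default_theta_star(depth: float = 0.5) -> np.ndarray:
    """A (210, 8) coefficient table forming a uniform attractive well.

    All coefficients equal -depth, so each pair contributes -depth times
    the basis sum: a smooth well that is flat on the partition-of-unity
    window [4, 9] Å and decays to zero outside [1, 12] Å.  The induced
    energy gap phi . theta* is then proportional to the number of residue
    pairs a decoy has pushed out of the interaction range relative to the
    native — a smooth contact-loss distance, positive whenever deformation
    expands the structure on balance.
    """
    from funnelpot.potentials import N_BASIS, N_PAIRS
    return np.full((N_PAIRS, N_BASIS), -depth)


#: noise grid of the planted-funnel recovery experiment.  A planted target
#: max(eps, phi . theta*) is only a funnel if the floor stays inactive;
#: because phi . theta* is linear in the perturbation, small-sigma decoys
#: have sign-symmetric targets, so the experiment uses deformations large
#: enough for the systematic expansion drift (~sigma^2) to dominate the
#: linear spread (~sigma), keeping essentially all targets positive.
PLANTED_NOISE_GRID = [4.0, 5.0, 6.0, 8.0]


def planted_experiment_config(seed: int, n_res: int = 40,
                              n_decoys: int = 100) -> SynthConfig:
    """Study conditions of the planted-funnel recovery experiment:
    40-residue proteins, 100 decoys each, large-deformation noise grid."""
    return SynthConfig(n_res=n_res, n_decoys=n_decoys,
                       noise_grid=list(PLANTED_NOISE_GRID), seed=seed)


def gen_planted_funnel(cfg: SynthConfig, theta_star: np.ndarray | None = None,
                       n_ensembles: int = 10, sigma_d: float = 0.0,
                       mode: str = "ppd", min_sep: int = 3,
                       ) -> tuple[list[DecoyEnsemble], list[np.ndarray]]:
    """Ensembles with a planted linear energy-distance funnel.

    For each of ``n_ensembles`` synthetic proteins, per-decoy target
    distances are d_ij = max(eps, phi_ij . theta* + noise) with phi the
    training feature gaps, theta* the planted coefficient table, and
    optional Gaussian noise sigma_d on the targets.  Returns
    (ensembles, targets) ready for the trainer, with theta* as ground
    truth.
    """
    from funnelpot.potentials import PotentialParams
    from funnelpot.training import featurize

    theta = default_theta_star() if theta_star is None else \
        np.asarray(theta_star, dtype=float)
    PotentialParams(theta)  # validates shape/finiteness
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta_star must be finite")

    ensembles: list[DecoyEnsemble] = []
    targets: list[np.ndarray] = []
    for i in range(n_ensembles):
        rng = _rng(cfg.seed, stream=2 + i)
        native = gen_native(cfg, rng)
        native = ChainModel(id=f"synth_{i:02d}", seq=native.seq,
                            coords=native.coords,
                            backbone_complete=native.backbone_complete)
        e = gen_decoys(native, cfg, rng, provenance=f"planted funnel {i}")
        Phi, _ = featurize(e, mode=mode, d_measure=None, min_sep=min_sep)
        raw = Phi @ theta.reshape(-1)
        if sigma_d > 0:
            raw = raw + rng.normal(scale=sigma_d, size=raw.shape)
        targets.append(np.maximum(PLANTED_EPS, raw))
        ensembles.append(e)
    return ensembles, targets


def gen_heldout(ensembles: list[DecoyEnsemble], cfg: SynthConfig,
                theta_star: np.ndarray | None = None, mode: str = "ppd",
                min_sep: int = 3,
                ) -> tuple[list[DecoyEnsemble], list[np.ndarray]]:
    """Fresh decoys (and planted targets) for the natives of existing
    planted-funnel ensembles, drawn from independent random streams."""
    from funnelpot.training import featurize

    theta = default_theta_star() if theta_star is None else \
        np.asarray(theta_star, dtype=float)
    held, targets = [], []
    for i, e in enumerate(ensembles):
        rng = _rng(cfg.seed, stream=1000 + i)
        h = gen_decoys(e.native, cfg, rng, provenance=f"held-out {i}")
        Phi, _ = featurize(h, mode=mode, d_measure=None, min_sep=min_sep)
        targets.append(np.maximum(PLANTED_EPS, Phi @ theta.reshape(-1)))
        held.append(h)
    return held, targets
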