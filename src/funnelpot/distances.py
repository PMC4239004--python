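"""Native-decoy distance measures.

Two extrinsic measures compare structures after optimal rigid superposition:
RMSD and GDT-TS* (= 1 - GDT-TS).  Two intrinsic measures compare internal
geometry only: Q* (= 1 - Q, the fraction of native contacts retained) and
the elastic deformation energies FlexE (harmonic) and MT (its Toda-form
anharmonic variant, which penalizes contact compression more than
extension).  All measures are zero when decoy equals native.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.spatial.transform import Rotation

from funnelpot.errors import DegenerateInputError
from funnelpot.structures import ChainModel

#: default Cα-Cα contact threshold in Å
CONTACT_THRESHOLD = 9.0
#: default minimum sequence separation |i-j| counted as a contact
MIN_SEP = 3
#: GDT-TS inclusion cutoffs in Å
GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ContactMap:
    """Symmetric binary residue-pair contact indicator.

    ``contacts[i, j]`` is True iff residues i and j are within ``threshold``
    Å and |i - j| >= ``min_sep``.  The diagonal band |i - j| < min_sep is
    always zero.
    """

    n: int
    contacts: np.ndarray  # (n, n) bool, symmetric
    threshold: float
    min_sep: int

    def __post_init__(self):
        c = np.asarray(self.contacts, dtype=bool)
        object.__setattr__(self, "contacts", c)
        if c.shape != (self.n, self.n):
            raise ValueError("contact matrix shape mismatch")
        if not np.array_equal(c, c.T):
            raise ValueError("contact matrix is not symmetric")
        ii, jj = np.indices(c.shape)
        if c[np.abs(ii - jj) < self.min_sep].any():
            raise ValueError("contacts inside the min_sep band")

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle contact indices (i < j)."""
        i, j = np.nonzero(np.triu(self.contacts))
        return i, j

    def count(self) -> int:
        return int(np.count_nonzero(np.triu(self.contacts)))


@dataclass(frozen=True)
class ElasticConfig:
    """Parameters of the elastic deformation energies FlexE and MT.

    ``k`` is the uniform spring constant (all force constants are set to 1),
    ``b`` the Toda shape parameter controlling the compression/extension
    asymmetry of MT, and ``contact_threshold`` the native contact cutoff.
    """

    k: float = 1.0
    b: float = 0.5
    contact_threshold: float = CONTACT_THRESHOLD
    min_sep: int = MIN_SEP

    def __post_init__(self):
        if self.k <= 0 or self.b <= 0 or self.contact_threshold <= 0:
            raise ValueError("k, b and contact_threshold must be positive")


def _check_pair(A: ChainModel, B: ChainModel, min_n: int = 1) -> int:
    if len(A) != len(B):
        raise DegenerateInputError(
            f"length mismatch: {len(A)} vs {len(B)} residues")
    if len(A) < min_n:
        raise DegenerateInputError(f"need at least {min_n} residues")
    return len(A)


def superpose(A: ChainModel, B: ChainModel) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid superposition of B onto A (Kabsch).

    Returns the transform G minimizing sum_i |x_i^A - G(x_i^B)|^2 together
    with the resulting RMSD.  Reflections are excluded; for degenerate
    (collinear) point sets the rotation about the free axis is the minimal
    one.
    """
    n = _check_pair(A, B, min_n=3)
    return _superpose_arrays(A.coords, B.coords)


def _superpose_arrays(a: np.ndarray, b: np.ndarray) -> tuple[RigidTransform, float]:
    if a.shape[0] < 3:
        raise DegenerateInputError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem restricted to
    # proper rotations, with minimal rotation in degenerate cases
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd_val = float(rssd) / np.sqrt(a.shape[0])
    return RigidTransform(rotation=R, translation=t), rmsd_val


def rmsd(A: ChainModel, B: ChainModel) -> float:
    """Cα RMSD after optimal rigid superposition (Å)."""
    return superpose(A, B)[1]


def _gdt_count(a: np.ndarray, b: np.ndarray, cutoff: float,
               seeds: list[np.ndarray], max_rounds: int = 10) -> int:
    """Largest count of residues superposable within ``cutoff``.

    Each seed fragment provides an initial superposition which is then
    refined: re-superpose on the current inlier set until it is stable.
    """
    n = a.shape[0]
    best = 0
    cutoff2 = cutoff * cutoff
    for seed in seeds:
        inliers = seed
        prev: np.ndarray | None = None
        for _ in range(max_rounds):
            if inliers.size < 3:
                break
            tf, _ = _superpose_arrays(a[inliers], b[inliers])
            d2 = np.sum((a - tf.apply(b)) ** 2, axis=1)
            new = np.flatnonzero(d2 <= cutoff2)
            if new.size > best:
                best = int(new.size)
            if prev is not None and np.array_equal(new, prev):
                break
            prev, inliers = inliers, new
        if best == n:
            break
    return best


def _gdt_seeds(n: int) -> list[np.ndarray]:
    stride = 2 if n > 200 else 1
    seeds: list[np.ndarray] = [np.arange(n)]
    for length in (3, 5, 7):
        if length > n:
            continue
        for start in range(0, n - length + 1, stride):
            seeds.append(np.arange(start, start + length))
    return seeds


def gdt_ts(A: ChainModel, B: ChainModel) -> float:
    """GDT-TS similarity in [0, 1].

    Mean over cutoffs 1/2/4/8 Å of the largest fraction of residues that
    can be rigidly superposed within the cutoff.  Candidate superpositions
    are seeded from every contiguous fragment of lengths 3, 5, 7 and the
    full chain, each refined iteratively on its inlier set (a deterministic
    LGA-style search).
    """
    n = _check_pair(A, B, min_n=3)
    seeds = _gdt_seeds(n)
    total = 0.0
    for cutoff in GDT_CUTOFFS:
        total += _gdt_count(A.coords, B.coords, cutoff, seeds) / n
    return total / len(GDT_CUTOFFS)


def gdt_ts_star(A: ChainModel, B: ChainModel) -> float:
    """GDT-TS* = 1 - GDT-TS, a distance in [0, 1]."""
    return 1.0 - gdt_ts(A, B)


def contact_map(m: ChainModel, threshold: float = CONTACT_THRESHOLD,
                min_sep: int = MIN_SEP) -> ContactMap:
    """Binary Cα contact map at ``threshold`` Å, |i-j| >= ``min_sep``."""
    d = squareform(pdist(m.coords))
    ii, jj = np.indices(d.shape)
    contacts = (d <= threshold) & (np.abs(ii - jj) >= min_sep)
    return ContactMap(n=len(m), contacts=contacts,
                      threshold=threshold, min_sep=min_sep)


def q_fraction(native: ChainModel, decoy: ChainModel,
               threshold: float = CONTACT_THRESHOLD,
               min_sep: int = MIN_SEP) -> float:
    """Fraction Q of native contacts retained by the decoy.

    Q = sc / (sc + lc) with sc the shared and lc the lost native contacts.
    Non-native contacts gained by the decoy are ignored.  A native with no
    contacts gives Q = 1 by convention (nothing to lose).
    """
    _check_pair(native, decoy)
    cn = contact_map(native, threshold, min_sep).contacts
    cd = contact_map(decoy, threshold, min_sep).contacts
    n_native = int(np.count_nonzero(np.triu(cn)))
    if n_native == 0:
        return 1.0
    shared = int(np.count_nonzero(np.triu(cn & cd)))
    return shared / n_native


def q_star(native: ChainModel, decoy: ChainModel,
           threshold: float = CONTACT_THRESHOLD,
           min_sep: int = MIN_SEP) -> float:
    """Q* = 1 - Q, the fraction of native contacts lost."""
    return 1.0 - q_fraction(native, decoy, threshold, min_sep)


def _contact_deltas(native: ChainModel, decoy: ChainModel,
                    cfg: ElasticConfig) -> np.ndarray:
    """d^D - d^N over the native contact pairs.

    The native structure's contact map is used for every native-decoy
    comparison, which keeps the deformation energies well defined.
    """
    _check_pair(native, decoy)
    cm = contact_map(native, cfg.contact_threshold, cfg.min_sep)
    i, j = cm.pairs
    dn = np.linalg.norm(native.coords[i] - native.coords[j], axis=1)
    dd = np.linalg.norm(decoy.coords[i] - decoy.coords[j], axis=1)
    return dd - dn


def flexe(native: ChainModel, decoy: ChainModel,
          cfg: ElasticConfig = ElasticConfig()) -> float:
    """Harmonic elastic deformation energy between native and decoy.

    Sum over native-contact pairs of (k/2)(d^D_ij - d^N_ij)^2; the energetic
    cost, in a uniform spring network, of deforming one structure into the
    other.
    """
    delta = _contact_deltas(native, decoy, cfg)
    return float(0.5 * cfg.k * np.sum(delta ** 2))


def mt(native: ChainModel, decoy: ChainModel,
       cfg: ElasticConfig = ElasticConfig()) -> float:
    """Toda-form anharmonic deformation energy.

    Per contact pair with Delta = d^D - d^N the term is
    (k/b^2)(exp(-b*Delta) - 1 + b*Delta): zero with zero slope at Delta=0,
    second-order Taylor expansion equal to the harmonic (k/2)Delta^2, and
    strictly larger for compression (-|Delta|) than extension (+|Delta|).
    """
    delta = _contact_deltas(native, decoy, cfg)
    b = cfg.b
    terms = (cfg.k / (b * b)) * (np.exp(-b * delta) - 1.0 + b * delta)
    return float(np.sum(terms))


MEASURES = ("RMSD", "GDT_TS_STAR", "Q_STAR", "MT", "FLEXE")

_MEASURE_ALIASES = {
    "rmsd": "RMSD", "gdt": "GDT_TS_STAR", "gdt_ts_star": "GDT_TS_STAR",
    "q": "Q_STAR", "q_star": "Q_STAR", "mt": "MT", "flexe": "FLEXE",
}


def normalize_measure_name(which: str) -> str:
    name = which.strip()
    key = name.upper() if name.upper() in MEASURES \
        else _MEASURE_ALIASES.get(name.lower())
    if key is None:
        raise ValueError(f"unknown distance measure {which!r}; "
                         f"choose from {MEASURES}")
    return key


def measure(native: ChainModel, decoy: ChainModel, which: str,
            cfg: ElasticConfig = ElasticConfig()) -> float:
    """Dispatch to one of the distance measures by name.

    Similarity-based measures are returned in their starred distance form
    (GDT-TS* and Q*), so every measure is 0 for decoy = native.
    """
    key = normalize_measure_name(which)
    if key == "RMSD":
        return rmsd(native, decoy)
    if key == "GDT_TS_STAR":
        return gdt_ts_star(native, decoy)
    if key == "Q_STAR":
        return q_star(native, decoy, cfg.contact_threshold, cfg.min_sep)
    if key == "MT":
        return mt(native, decoy, cfg)
    return flexe(native, decoy, cfg)
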