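"""Shared fixtures: small synthetic chains, PDB fixture writer, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from funnelpot.structures import ChainModel
from funnelpot.synthetic import SynthConfig, gen_decoys, gen_native


def make_chain(coords, seq=None, ident="chain", flags=None) -> ChainModel:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if seq is None:
        seq = "A" * n
    if flags is None:
        flags = np.ones(n, dtype=bool)
    return ChainModel(id=ident, seq=seq, coords=coords,
                      backbone_complete=np.asarray(flags, dtype=bool))


def straight_chain(n: int, spacing: float = 3.8, seq=None) -> ChainModel:
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return make_chain(coords, seq=seq, ident=f"line{n}")


def random_compact_chain(n: int, seed: int) -> ChainModel:
    cfg = SynthConfig(n_res=max(n, 5), n_decoys=1, seed=seed)
    m = gen_native(cfg, np.random.default_rng(seed))
    return m


POLY_ALA_PDB_TEMPLATE = """\
ATOM  {serial:>5} {name:<4}{altloc}{resname:>3} {chain}{resseq:>4}{icode}   \
{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}
"""


def write_pdb_fixture(path, coords, resname="ALA", omit=(),
                      altloc_extra=False):
    """Write a backbone-complete poly-residue PDB fixture.

    ``omit`` is a set of (residue_index, atom_name) pairs to leave out;
    ``altloc_extra`` adds a lower-occupancy altloc B for residue 0's CA,
    displaced by 5 Å.
    """
    coords = np.asarray(coords, dtype=float)
    offsets = {"N": (-1.46, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (1.52, 0.0, 0.0), "O": (1.52, 1.23, 0.0)}
    lines = []
    serial = 1

    def record(name, altloc, resseq, xyz, occ):
        nonlocal serial
        lines.append(POLY_ALA_PDB_TEMPLATE.format(
            serial=serial, name=f" {name}", altloc=altloc, resname=resname,
            chain="A", resseq=resseq, icode=" ", x=xyz[0], y=xyz[1],
            z=xyz[2], occ=occ, b=0.0, element=name[0]))
        serial += 1

    for i, xyz in enumerate(coords):
        for name in ("N", "CA", "C", "O"):
            if (i, name) in omit:
                continue
            use_altloc = altloc_extra and i == 0 and name == "CA"
            record(name, "A" if use_altloc else " ", i + 1,
                   xyz + np.array(offsets[name]), 0.7 if use_altloc else 1.0)
            if use_altloc:
                record("CA", "B", i + 1, xyz + np.array([5.0, 0.0, 0.0]), 0.3)
    with open(path, "w") as fh:
        fh.writelines(lines)
        fh.write("END\n")


@pytest.fixture
def small_ensemble():
    """30-residue compact native with 20 decoys over the default grid."""
    cfg = SynthConfig(n_res=30, n_decoys=20, seed=7)
    native = gen_native(cfg)
    return gen_decoys(native, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
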