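"""Read C-alpha models from PDB files and harmonize native/decoy ensembles.

Decoy collections are rarely length-consistent: decoys may miss backbone
atoms for some residues, or miss leading/trailing residues entirely.
Preprocessing is two-step: (1) remove residues with incomplete backbone
(Cα, N, C, O) from every model, (2) align each decoy sequence against the
native and trim unmatched *trailing* residues from either side until all
sequences are identical.  Internal mismatches or gaps are rejected rather
than resolved — end-trimming is the only repair this pipeline performs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from funnelpot.errors import EmptyModelError, HarmonizationError, PDBParseError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)
BACKBONE_ATOMS = ("CA", "N", "C", "O")

#: three-letter -> one-letter for the 20 standard residues plus common
#: unambiguous variants (modified residues mapped to their parent).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}


@dataclass(frozen=True)
class ChainModel:
    """One structural model: sequence plus ordered Cα coordinates.

    Parameters
    ----------
    id : str
        Free-text label (file stem, decoy id, ...).
    seq : str
        One-letter amino-acid codes, length N.
    coords : ndarray, shape (N, 3)
        Cα positions in Ångström, file order.
    backbone_complete : ndarray of bool, shape (N,)
        True where the residue has all four backbone atoms (Cα, N, C, O).
    """

    id: str
    seq: str
    coords: np.ndarray
    backbone_complete: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        flags = np.asarray(self.backbone_complete, dtype=bool)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "backbone_complete", flags)
        n = len(self.seq)
        if coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match sequence length {n}"
            )
        if flags.shape != (n,):
            raise ValueError("backbone_complete length does not match sequence")
        if n == 0:
            raise EmptyModelError(f"model {self.id!r} has zero residues")
        bad = set(self.seq) - _STANDARD_SET
        if bad:
            raise ValueError(f"non-standard residue codes in sequence: {sorted(bad)}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"model {self.id!r} has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.seq)

    def subset(self, idx: np.ndarray, new_id: str | None = None) -> "ChainModel":
        """Model restricted to residue positions ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return ChainModel(
            id=new_id or self.id,
            seq="".join(self.seq[i] for i in idx),
            coords=self.coords[idx],
            backbone_complete=self.backbone_complete[idx],
        )


@dataclass
class DecoyEnsemble:
    """A native model together with its length-harmonized decoys."""

    native: ChainModel
    decoys: list[ChainModel]
    provenance: str = ""

    def __post_init__(self):
        if not self.decoys:
            raise ValueError("ensemble needs at least one decoy")
        for d in self.decoys:
            if d.seq != self.native.seq:
                raise ValueError(
                    f"decoy {d.id!r} sequence differs from native "
                    f"(harmonize the ensemble first)"
                )

    @property
    def n_res(self) -> int:
        return len(self.native)

    def __len__(self) -> int:
        return len(self.decoys)


def _residue_one_letter(name: str) -> str | None:
    code = THREE_TO_ONE.get(name.upper())
    if code is not None:
        return code
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one in _STANDARD_SET:
            return one
    return None


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the first-listed conformer
    return max(atoms, key=lambda a: a.occ) if len(atoms) > 1 else atoms[0]


def read_ca_model(path: str, chain: str | None = None) -> ChainModel:
    """Read a Cα chain model from a PDB file.

    Only the first MODEL of multi-model files is read; HETATM records and
    waters are ignored.  ``chain`` selects a chain by name; by default the
    first chain containing an amino-acid Cα is used.  Residues whose name
    cannot be mapped to a standard amino acid are dropped with a warning.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]

    selected = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        if any(res.find_atom("CA", "*") is not None and not res.het_flag == "H"
               for res in ch):
            selected = ch
            break
    if selected is None:
        raise EmptyModelError(
            f"{path}: no chain with Cα atoms" +
            (f" (chain {chain!r} requested)" if chain else "")
        )

    seq: list[str] = []
    coords: list[list[float]] = []
    flags: list[bool] = []
    for res in selected:
        if res.het_flag == "H" and res.name not in THREE_TO_ONE:
            continue
        one = _residue_one_letter(res.name)
        if one is None:
            warnings.warn(
                f"{path}: dropping unmappable residue {res.name} "
                f"{res.seqid.num}", stacklevel=2)
            continue
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            if atom.name in BACKBONE_ATOMS:
                by_name.setdefault(atom.name, []).append(atom)
        if "CA" not in by_name:
            continue
        ca = _pick_altloc(by_name["CA"])
        seq.append(one)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        flags.append(all(name in by_name for name in BACKBONE_ATOMS))

    if not seq:
        raise EmptyModelError(f"{path}: zero Cα atoms in selected chain")
    import os
    label = os.path.splitext(os.path.basename(str(path)))[0]
    return ChainModel(id=label, seq="".join(seq),
                      coords=np.array(coords, dtype=float),
                      backbone_complete=np.array(flags, dtype=bool))


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3
                 and k not in ("MSE", "SEC", "PYL", "HYP", "SEP", "TPO",
                               "PTR", "CSO", "MLY")}

#: fixed local offsets used to emit placeholder N/C/O positions for
#: Cα-only models, so written files round-trip as backbone-complete.
_BACKBONE_OFFSETS = {"N": (-1.46, 0.0, 0.0), "C": (1.52, 0.0, 0.0),
                     "O": (1.52, 1.23, 0.0)}


def write_ca_model(m: ChainModel, path: str, chain: str = "A") -> None:
    """Write a ChainModel as a PDB file.

    The package stores Cα positions only.  For residues flagged
    backbone-complete, placeholder N/C/O atoms are written at fixed offsets
    from the Cα so the completeness flag survives a round-trip; downstream
    computations consume Cα coordinates exclusively.
    """
    st = gemmi.Structure()
    st.name = m.id
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, (aa, xyz, ok) in enumerate(zip(m.seq, m.coords, m.backbone_complete)):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE[aa]
        res.seqid = gemmi.SeqId(i + 1, " ")
        atoms = [("CA", xyz)]
        if ok:
            atoms += [(name, xyz + np.array(off))
                      for name, off in _BACKBONE_OFFSETS.items()]
        for name, pos in atoms:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def drop_incomplete_residues(m: ChainModel) -> ChainModel:
    """Remove residues with missing backbone atoms (order preserved)."""
    keep = np.flatnonzero(m.backbone_complete)
    if keep.size == 0:
        raise EmptyModelError(
            f"model {m.id!r}: no residues with complete backbone")
    if keep.size == len(m):
        return m
    return m.subset(keep)


def _best_end_gap_alignment(native: str, decoy: str) -> tuple[int, int, int]:
    """Best global alignment of ``decoy`` to ``native`` with identity
    scoring, mismatches disallowed, and gaps only at the ends.

    Under that scoring the optimal alignment is a relative shift: native
    position ``i`` pairs with decoy position ``i - offset`` over the
    overlap window.  Returns ``(offset, start, end)`` with the window
    ``[start, end)`` in native coordinates.  Raises HarmonizationError if
    no shift yields a mismatch-free overlap (an internal edit).
    """
    nn, nd = len(native), len(decoy)
    best: tuple[int, int, int] | None = None
    best_key: tuple[int, int, int] | None = None
    for offset in range(-(nd - 1), nn):
        start = max(0, offset)
        end = min(nn, nd + offset)
        if end <= start:
            continue
        if native[start:end] != decoy[start - offset:end - offset]:
            continue
        key = (-(end - start), abs(offset), offset)  # longest, then centred
        if best_key is None or key < best_key:
            best_key = key
            best = (offset, start, end)
    if best is None:
        raise HarmonizationError(
            "no end-gap-only alignment exists (internal mismatch or gap)")
    return best


def harmonize_ensemble(native: ChainModel,
                       decoys: list[ChainModel],
                       provenance: str = "") -> DecoyEnsemble:
    """Trim leading/trailing unmatched residues until native and all decoys
    share one identical sequence.

    Each decoy sequence is globally aligned to the native with identity
    scoring and end gaps only; the harmonized region is the intersection of
    all overlap windows.  A decoy whose sequence cannot be reconciled by
    end-trimming raises HarmonizationError naming the decoy.
    """
    if not decoys:
        raise ValueError("harmonize_ensemble needs at least one decoy")
    lo, hi = 0, len(native)
    offsets: list[int] = []
    for d in decoys:
        try:
            offset, start, end = _best_end_gap_alignment(native.seq, d.seq)
        except HarmonizationError as exc:
            raise HarmonizationError(f"decoy {d.id!r}: {exc}") from exc
        offsets.append(offset)
        lo, hi = max(lo, start), min(hi, end)
    if hi <= lo:
        raise HarmonizationError("empty sequence intersection across decoys")

    window = np.arange(lo, hi)
    new_native = native.subset(window)
    new_decoys = [d.subset(window - off) for d, off in zip(decoys, offsets)]
    return DecoyEnsemble(native=new_native, decoys=new_decoys,
                         provenance=provenance)
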