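"""PDB structure input/output and mutation specifications.

The in-memory model is deliberately lightweight — ordered residues carrying
ordered atoms with coordinates — because every downstream feature (surface
area, dihedrals, distance signatures) works directly on coordinates.
Parsing is delegated to Biopython's ``Bio.PDB`` parser; this module layers
the policies on top: first model only, waters and hetero groups dropped
(selenomethionine kept, mapped to methionine), alternate locations resolved
to the highest-occupancy conformer with ties broken by file order.

Residue numbering is the author numbering from the file (plus insertion
code); no renumbering is performed.
"""
from __future__ import annotations

import copy as _copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be turned into a usable structure."""


class MutationError(ValueError):
    """Raised for invalid or inconsistent mutation specifications."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray          # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    aa: str                    # one-letter code, 'X' for unknowns
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    model_index: int = 0

    def get_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, seq_num, icode):
                return r
        return None

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class Mutation:
    chain_id: str
    seq_num: int
    icode: str
    wt_aa: str
    mut_aa: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.seq_num}{self.icode}{self.mut_aa} (chain {self.chain_id})"


def _validate_coordinate_lines(path: str) -> None:
    """Raise PDBParseError naming the line if an ATOM record is unreadable."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: unreadable coordinates at line {lineno}"
                    ) from None


def read_pdb(path: str, model_policy: str = "first") -> Structure:
    """Parse a PDB file into a :class:`Structure` (first model only).

    Hetero groups and waters are excluded, except selenomethionine (MSE)
    which is kept as methionine with SE renamed to SD.  Alternate locations
    collapse to the highest-occupancy conformer (ties: first in file).
    Non-standard residues other than MSE are dropped with a warning.
    """
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy: {model_policy!r}")
    _validate_coordinate_lines(path)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio_structure = parser.get_structure("input", path)
        except Exception as exc:  # Bio.PDB raises plain exceptions on malformed files
            raise PDBParseError(f"{path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, seq_num, icode = res.id
            if hetflag == "W":
                continue
            resname = res.get_resname().strip()
            is_mse = resname == "MSE"
            if hetflag.strip() and not is_mse:
                continue
            if resname not in AA3_TO_1 and not is_mse:
                logger.warning("dropping non-standard residue %s %s%s", resname, chain.id, seq_num)
                continue
            aa = "M" if is_mse else AA3_TO_1[resname]
            atoms: list[Atom] = []
            for bio_atom in res:
                # DisorderedAtom: Bio.PDB pre-selects the highest-occupancy
                # altloc (first in file on ties), matching our policy.
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                name = bio_atom.get_name()
                element = (bio_atom.element or "").strip() or name[:1]
                if is_mse and name == "SE":
                    name, element = "SD", "S"
                atoms.append(Atom(
                    name=name,
                    element=element.upper(),
                    coord=np.asarray(bio_atom.get_coord(), dtype=float),
                    occupancy=float(bio_atom.get_occupancy() or 1.0),
                    altloc=bio_atom.get_altloc().strip(),
                    b_factor=float(bio_atom.get_bfactor() or 0.0),
                ))
            if atoms:
                residues.append(Residue(chain.id, seq_num, icode.strip(), aa, atoms))

    if not residues:
        raise PDBParseError(f"{path}: no standard protein residues found")
    if not any(r.atom("CA") for r in residues):
        raise PDBParseError(f"{path}: no residue has a CA atom")
    return Structure(id=bio_structure.id, residues=residues, model_index=0)


def write_pdb(structure: Structure, path: str) -> None:
    """Write a Structure as PDB v3.3 ATOM records (single model)."""
    serial = 1
    lines: list[str] = []
    for res in structure.residues:
        res3 = AA1_TO_3.get(res.aa, "UNK")
        for atom in res.atoms:
            name = atom.name
            # standard PDB name alignment: element code starts in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {padded:<4s}{'':1s}{res3:>3s} {res.chain_id:1s}"
                f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_mutation(spec: str, chain_id: str, structure: Structure, icode: str = "") -> Mutation:
    """Parse ``"<WT><pos><MUT>"`` (e.g. ``"A17G"``) and validate it against the structure."""
    spec = spec.strip()
    if len(spec) < 3 or not spec[0].isalpha() or not spec[-1].isalpha():
        raise MutationError(f"malformed mutation spec: {spec!r} (expected e.g. 'A17G')")
    wt, mut = spec[0].upper(), spec[-1].upper()
    pos_part = spec[1:-1]
    if not pos_part.isdigit():
        raise MutationError(f"malformed mutation spec: {spec!r} (position must be an integer)")
    seq_num = int(pos_part)
    if wt not in STANDARD_AA:
        raise MutationError(f"wild-type code {wt!r} is not a standard amino acid")
    if mut not in STANDARD_AA:
        raise MutationError(f"mutant code {mut!r} is not a standard amino acid")
    res = structure.get_residue(chain_id, seq_num, icode)
    if res is None:
        raise MutationError(f"no residue at chain {chain_id} position {seq_num}{icode}")
    if res.aa != wt:
        raise MutationError(
            f"wild-type mismatch at {chain_id}{seq_num}: spec says {wt}, structure has {res.aa}"
        )
    return Mutation(chain_id, seq_num, icode, wt, mut)


def enumerate_mutants(structure: Structure, chain_id: str, seq_num: int,
                      icode: str = "") -> list[Mutation]:
    """All 19 single mutations at a position, alphabetical by mutant code."""
    res = structure.get_residue(chain_id, seq_num, icode)
    if res is None:
        raise MutationError(f"no residue at chain {chain_id} position {seq_num}{icode}")
    return [
        Mutation(chain_id, seq_num, icode, res.aa, m)
        for m in sorted(STANDARD_AA)
        if m != res.aa
    ]


def build_mutant_placeholder(structure: Structure, mutation: Mutation) -> Structure:
    """Relabel the mutated residue and truncate its side chain beyond CB.

    This is a naive placeholder, not a modelled mutant: the predictor's
    features are computed from the wild-type environment plus residue-type
    deltas, so only the label and a minimal consistent geometry are needed.
    """
    out = structure.copy()
    res = out.get_residue(mutation.chain_id, mutation.seq_num, mutation.icode)
    if res is None:
        raise MutationError(f"no residue at {mutation}")
    if res.aa != mutation.wt_aa:
        raise MutationError(f"wild-type mismatch applying {mutation}: structure has {res.aa}")
    if mutation.wt_aa == mutation.mut_aa:
        return out
    keep = {"N", "CA", "C", "O", "OXT"}
    if mutation.mut_aa != "G":
        keep.add("CB")
    res.atoms = [a for a in res.atoms if a.name in keep]
    res.aa = mutation.mut_aa
    return out
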