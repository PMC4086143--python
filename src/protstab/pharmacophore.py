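"""Pharmacophore atom typing and residue count vectors.

Each heavy atom of a standard residue is assigned to one or more of eight
atom characteristics: hydrophobic, positive, negative, hydrogen acceptor,
hydrogen donor, aromatic, sulphur, neutral.  A residue's pharmacophore
vector counts class memberships over its standard heavy atoms (backbone
included); the change vector of a mutation is wild type minus mutant,
component-wise, and may be negative.

Assignments live in a packaged table (``data/atom_classes.tsv``) following
standard conventions: carboxylate oxygens are negative + acceptor,
Lys/Arg/His nitrogen cations are positive + donor, ring atoms of F/Y/W/H are
aromatic (carbons also hydrophobic), backbone O is an acceptor and backbone
N a donor (except proline), aliphatic carbons are hydrophobic, sulphur atoms
of Cys/Met form the sulphur class, and polar-adjacent carbons (amide,
carboxylate and guanidinium carbons, Lys CE) are neutral.  An atom may
belong to several classes, so components are independent counts, not a
partition.
"""
from __future__ import annotations

import csv
import logging
from functools import lru_cache
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

CLASSES = ("hydrophobic", "positive", "negative", "hydrogen_acceptor",
           "hydrogen_donor", "aromatic", "sulphur", "neutral")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES = len(CLASSES)

# carboxy-terminal oxygen is not part of any residue's standard composition
_EXTRA_ATOMS = {"OXT": frozenset({"hydrogen_acceptor", "negative"})}


@lru_cache(maxsize=1)
def _load_table(path: str | None = None) -> dict[tuple[str, str], frozenset[str]]:
    if path is None:
        source = resources.files("protstab.data").joinpath("atom_classes.tsv")
        fh = source.open("r")
    else:
        fh = open(path)
    table: dict[tuple[str, str], frozenset[str]] = {}
    with fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            classes = frozenset(row["classes"].split(","))
            unknown = classes - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown pharmacophore classes {unknown} in table")
            table[(row["residue"], row["atom"])] = classes
    return table


def atom_classes(aa: str, atom_name: str, table_path: str | None = None) -> frozenset[str]:
    """Pharmacophore classes of one heavy atom; empty set with a warning if
    the atom name is not part of the residue's standard composition."""
    table = _load_table(table_path)
    key = (aa, atom_name)
    if key in table:
        return table[key]
    if atom_name in _EXTRA_ATOMS:
        return _EXTRA_ATOMS[atom_name]
    logger.warning("no pharmacophore assignment for atom %s of residue %s", atom_name, aa)
    return frozenset()


def residue_atoms(aa: str, table_path: str | None = None) -> list[str]:
    """Standard heavy-atom names of a residue, backbone first, in table order."""
    table = _load_table(table_path)
    return [atom for (res, atom) in table if res == aa]


def residue_vector(aa: str, table_path: str | None = None) -> np.ndarray:
    """8-component pharmacophore count vector over the residue's standard
    heavy atoms (backbone included)."""
    table = _load_table(table_path)
    counts = np.zeros(N_CLASSES, dtype=int)
    found = False
    for (res, _atom), classes in table.items():
        if res != aa:
            continue
        found = True
        for c in classes:
            counts[CLASS_INDEX[c]] += 1
    if not found:
        raise KeyError(f"no pharmacophore table entries for residue {aa!r}")
    return counts


def change_vector(wt: str, mut: str, table_path: str | None = None) -> np.ndarray:
    """Signed wild-type minus mutant pharmacophore count difference."""
    return residue_vector(wt, table_path) - residue_vector(mut, table_path)


def atom_indicator(aa: str, atom_name: str, table_path: str | None = None) -> np.ndarray:
    """0/1 class membership vector of one atom (length 8)."""
    ind = np.zeros(N_CLASSES, dtype=int)
    for c in atom_classes(aa, atom_name, table_path):
        ind[CLASS_INDEX[c]] = 1
    return ind
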