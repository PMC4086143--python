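"""Per-residue structural environment: solvent accessibility, secondary
structure and side-chain hydrogen-bond satisfaction.

Solvent-accessible surface area is computed with the Shrake-Rupley
point-sampling scheme on a deterministic Fibonacci sphere lattice, tracing
the surface accessible to a 1.4 A water probe.  Relative solvent
accessibility (RSA) divides a residue's area by its maximum reference
accessibility in an extended Gly-X-Gly tripeptide.  Secondary structure is a
coarse 3-state assignment (helix / strand / coil) from backbone phi/psi
windows, which is all the downstream consensus feature consumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import dihedral, fibonacci_sphere
from .config import Config, SasaConfig, SecondaryStructureConfig
from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

SS_CLASSES = ("helix", "strand", "coil")

# residues whose side chain carries no hydrogen-bond donor/acceptor heavy atom
_APOLAR_SIDECHAINS = set("AVLIFGPM")


class UnknownElementError(ValueError):
    pass


@dataclass
class EnvironmentFeatures:
    rsa: float                      # fraction in [0, 1]
    ss_class: str                   # helix | strand | coil
    sidechain_hbond_satisfied: bool
    sasa_abs: float                 # A^2


def atom_sasa(structure: Structure, probe_radius: float | None = None,
              n_points: int | None = None,
              radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area for all atoms, in structure order.

    Each atom's sphere of radius vdW + probe is sampled at ``n_points``
    lattice points; the accessible fraction times the sphere area is its
    SASA contribution.
    """
    defaults = SasaConfig()
    if probe_radius is None:
        probe_radius = defaults.probe_radius
    if n_points is None:
        n_points = defaults.n_sphere_points
    cfg_radii = radii if radii is not None else defaults.radii
    atoms = [a for r in structure.residues for a in r.atoms]
    coords = np.array([a.coord for a in atoms])
    try:
        rads = np.array([cfg_radii[a.element] for a in atoms])
    except KeyError:
        missing = sorted({a.element for a in atoms if a.element not in cfg_radii})
        raise UnknownElementError(
            f"no van der Waals radius for element(s): {', '.join(missing)}"
        ) from None
    ext = rads + probe_radius
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + ext[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    return areas


def compute_sasa(structure: Structure, probe_radius: float | None = None,
                 n_points: int | None = None,
                 radii: dict[str, float] | None = None
                 ) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA (A^2): atom areas summed by residue."""
    areas = atom_sasa(structure, probe_radius, n_points, radii)
    out: dict[tuple[str, int, str], float] = {}
    i = 0
    for res in structure.residues:
        n = len(res.atoms)
        out[res.key] = float(areas[i:i + n].sum())
        i += n
    return out


def compute_rsa(sasa_abs: float, aa: str, max_acc: dict[str, float] | None = None) -> float:
    """Relative solvent accessibility in [0, 1] (clamped)."""
    table = max_acc if max_acc is not None else SasaConfig().max_acc
    if aa not in table:
        raise KeyError(f"no reference accessibility for residue {aa!r}")
    return float(np.clip(sasa_abs / table[aa], 0.0, 1.0))


def backbone_dihedrals(structure: Structure) -> dict[tuple[str, int, str], tuple[float | None, float | None]]:
    """(phi, psi) per residue in degrees; None where undefined (termini,
    missing backbone atoms)."""
    out: dict[tuple[str, int, str], tuple[float | None, float | None]] = {}
    chains: dict[str, list[Residue]] = {}
    for r in structure.residues:
        chains.setdefault(r.chain_id, []).append(r)
    for chain_residues in chains.values():
        for i, res in enumerate(chain_residues):
            phi = psi = None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if None not in (n, ca, c):
                if i > 0:
                    prev_c = chain_residues[i - 1].atom("C")
                    if prev_c is not None:
                        phi = dihedral(prev_c.coord, n.coord, ca.coord, c.coord)
                if i < len(chain_residues) - 1:
                    next_n = chain_residues[i + 1].atom("N")
                    if next_n is not None:
                        psi = dihedral(n.coord, ca.coord, c.coord, next_n.coord)
            else:
                logger.warning("missing backbone atoms at %s%s; dihedrals undefined",
                               res.chain_id, res.seq_num)
            out[res.key] = (phi, psi)
    return out


def _in_window(value: float | None, window: tuple[float, float]) -> bool:
    return value is not None and window[0] <= value <= window[1]


def assign_secondary_structure(structure: Structure,
                               ss_cfg: SecondaryStructureConfig | None = None
                               ) -> dict[tuple[str, int, str], str]:
    """3-state secondary structure from phi/psi windows.

    A residue is helix when its dihedrals fall in the helical window as part
    of a run of at least ``helix_min_run`` consecutive such residues; strand
    analogously with ``strand_min_run``; everything else (including chain
    termini, whose dihedrals are undefined) is coil.
    """
    cfg = ss_cfg or SecondaryStructureConfig()
    dihedrals = backbone_dihedrals(structure)

    chains: dict[str, list[Residue]] = {}
    for r in structure.residues:
        chains.setdefault(r.chain_id, []).append(r)

    out: dict[tuple[str, int, str], str] = {}
    for chain_residues in chains.values():
        flags = []
        for res in chain_residues:
            phi, psi = dihedrals[res.key]
            is_h = _in_window(phi, cfg.helix_phi) and _in_window(psi, cfg.helix_psi)
            is_e = _in_window(phi, cfg.strand_phi) and (
                _in_window(psi, cfg.strand_psi) or _in_window(psi, cfg.strand_psi_wrap))
            flags.append((is_h, is_e))

        classes = ["coil"] * len(chain_residues)
        for label, idx, min_run in (("helix", 0, cfg.helix_min_run),
                                    ("strand", 1, cfg.strand_min_run)):
            start = 0
            while start < len(flags):
                if flags[start][idx]:
                    end = start
                    while end < len(flags) and flags[end][idx]:
                        end += 1
                    if end - start >= min_run:
                        for k in range(start, end):
                            classes[k] = label
                    start = end
                else:
                    start += 1
        for res, cls in zip(chain_residues, classes):
            out[res.key] = cls
    return out


def sidechain_hbond_satisfaction(structure: Structure, residue: Residue,
                                 cutoff: float = 3.5) -> bool:
    """True iff every side-chain donor/acceptor heavy atom (N/O/S beyond CB)
    has a polar heavy atom (N or O) of a *different* residue within ``cutoff``.

    Residues with no polar side-chain atoms are vacuously satisfied.
    """
    donors = [a for a in residue.atoms
              if a.is_sidechain and a.element in ("N", "O", "S")]
    if not donors:
        return True
    partners = np.array([
        a.coord
        for res in structure.residues if res.key != residue.key
        for a in res.atoms if a.element in ("N", "O")
    ])
    if partners.size == 0:
        return False
    for atom in donors:
        d = np.linalg.norm(partners - atom.coord, axis=1)
        if not (d <= cutoff).any():
            return False
    return True


def compute_environment(structure: Structure, config: Config | None = None
                        ) -> dict[tuple[str, int, str], EnvironmentFeatures]:
    """All environment features for every residue of a structure."""
    cfg = config or Config()
    sasa = compute_sasa(structure, cfg.sasa.probe_radius, cfg.sasa.n_sphere_points,
                        cfg.sasa.radii)
    ss = assign_secondary_structure(structure, cfg.ss)
    out = {}
    for res in structure.residues:
        area = sasa[res.key]
        rsa = compute_rsa(area, res.aa, cfg.sasa.max_acc) if res.aa in cfg.sasa.max_acc else 0.0
        out[res.key] = EnvironmentFeatures(
            rsa=rsa,
            ss_class=ss[res.key],
            sidechain_hbond_satisfied=sidechain_hbond_satisfaction(
                structure, res, cfg.hbond_cutoff),
            sasa_abs=area,
        )
    return out
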