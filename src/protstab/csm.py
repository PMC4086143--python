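"""Cutoff Scanning Matrix signatures of a mutation's structural environment.

The environment of a mutation site — every residue with at least one atom
within a cutoff radius of the site — is summarised as cumulative counts of
pharmacophore-labelled atom pairs within a sweep of distance cutoffs.  The
result is a distance-pattern fingerprint of the 3D physicochemical
neighbourhood: for each cutoff shell and each unordered pair of the eight
atom classes, the number of atom pairs no farther apart than the cutoff in
which one atom carries the first class and the other the second.

Because the signature depends only on interatomic distances it is exactly
invariant under rigid rotation and translation, and cumulative counts are
monotone non-decreasing along the shell axis by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import CsmConfig
from .pharmacophore import N_CLASSES, atom_indicator
from .structure_io import Atom, Mutation, Structure

# unordered class-pair categories: (p, q) with p <= q, row-major
PAIR_CATEGORIES: list[tuple[int, int]] = [
    (p, q) for p in range(N_CLASSES) for q in range(p, N_CLASSES)
]
N_CATEGORIES = len(PAIR_CATEGORIES)  # 8 * 9 / 2 = 36
_CAT_INDEX = {pq: k for k, pq in enumerate(PAIR_CATEGORIES)}


@dataclass
class CSMSignature:
    d_min: float
    d_max: float
    step: float
    environment_radius: float
    shell_counts: np.ndarray  # (n_shells, 36) cumulative int counts

    @property
    def n_shells(self) -> int:
        return self.shell_counts.shape[0]

    @property
    def cutoffs(self) -> np.ndarray:
        return self.d_min + self.step * np.arange(self.n_shells)

    def flatten(self) -> np.ndarray:
        """Fixed flattening order: shells-major, category-minor."""
        return self.shell_counts.reshape(-1)


def environment_atoms(structure: Structure, mutation: Mutation,
                      radius: float) -> list[tuple[str, Atom]]:
    """Heavy atoms (with their residue's amino acid) of all residues having
    at least one atom within ``radius`` of any atom of the mutated residue,
    the mutated residue included."""
    site = structure.get_residue(mutation.chain_id, mutation.seq_num, mutation.icode)
    if site is None:
        raise KeyError(f"no residue at {mutation}")
    site_coords = np.array([a.coord for a in site.atoms])
    out: list[tuple[str, Atom]] = []
    for res in structure.residues:
        coords = np.array([a.coord for a in res.atoms])
        d = np.linalg.norm(site_coords[:, None, :] - coords[None, :, :], axis=2)
        if d.min() <= radius:
            out.extend((res.aa, a) for a in res.heavy_atoms())
    return out


def compute_signature(atoms: list[tuple[str, Atom]], d_min: float, d_max: float,
                      step: float, environment_radius: float = float("nan")
                      ) -> CSMSignature:
    """Cumulative pharmacophore-pair counts over the distance-cutoff sweep.

    For each cutoff c = d_min + k*step and each unordered class pair {p, q},
    counts atom pairs (i < j) with distance <= c where atom i carries p and
    atom j carries q; multi-class atoms contribute to every class pair they
    span.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    n_shells = int(np.floor((d_max - d_min) / step + 1e-9)) + 1

    per_shell = np.zeros((n_shells, N_CATEGORIES), dtype=np.int64)
    if len(atoms) >= 2:
        coords = np.array([a.coord for _aa, a in atoms])
        U = np.array([atom_indicator(aa, a.name) for aa, a in atoms])  # (n, 8)
        dist = squareform(pdist(coords))
        iu, ju = np.triu_indices(len(atoms), k=1)
        d = dist[iu, ju]
        # shell index = first cutoff >= distance
        k = np.ceil((d - d_min) / step - 1e-9).astype(int)
        k = np.maximum(k, 0)
        ok = d <= d_max + 1e-9
        for shell in range(n_shells):
            sel = ok & (k == shell)
            if not sel.any():
                continue
            A = U[iu[sel]].T @ U[ju[sel]]          # (8, 8) ordered pair counts
            sym = A + A.T
            for cat, (p, q) in enumerate(PAIR_CATEGORIES):
                per_shell[shell, cat] = A[p, p] if p == q else sym[p, q]
    cumulative = np.cumsum(per_shell, axis=0)
    return CSMSignature(d_min=d_min, d_max=d_max, step=step,
                        environment_radius=environment_radius,
                        shell_counts=cumulative)


def mutation_signature(structure: Structure, mutation: Mutation,
                       cfg: CsmConfig | None = None) -> CSMSignature:
    """Signature of the wild-type environment of a mutation site."""
    cfg = cfg or CsmConfig()
    atoms = environment_atoms(structure, mutation, cfg.environment_radius)
    sig = compute_signature(atoms, cfg.d_min, cfg.d_max, cfg.step,
                            environment_radius=cfg.environment_radius)
    return sig
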