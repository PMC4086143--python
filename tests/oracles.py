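"""Independent reference implementations used to cross-check the package.

These deliberately use different algorithms / code paths from the library:
a latitude-longitude surface quadrature instead of the Fibonacci lattice,
and plain nested-loop pair counting instead of the vectorised signature.
"""
from itertools import combinations

import numpy as np

from protstab.csm import N_CATEGORIES, PAIR_CATEGORIES
from protstab.pharmacophore import CLASSES, atom_classes
from protstab.structure_io import Atom


def lat_long_sasa(coords, radii, probe, spacing=0.1):
    """SASA by dense latitude-longitude band quadrature on each expanded sphere."""
    coords = np.asarray(coords, dtype=float)
    ext = np.asarray(radii, dtype=float) + probe
    total = np.zeros(len(coords))
    for i in range(len(coords)):
        R = ext[i]
        n_theta = max(4, int(np.pi * R / spacing))
        thetas = (np.arange(n_theta) + 0.5) * np.pi / n_theta
        area_acc = 0.0
        for theta in thetas:
            band_area = 2 * np.pi * R ** 2 * np.sin(theta) * (np.pi / n_theta)
            n_phi = max(4, int(2 * np.pi * R * np.sin(theta) / spacing))
            phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
            pts = coords[i] + R * np.column_stack([
                np.sin(theta) * np.cos(phis),
                np.sin(theta) * np.sin(phis),
                np.full(n_phi, np.cos(theta)),
            ])
            ok = np.ones(n_phi, dtype=bool)
            for j in range(len(coords)):
                if j == i:
                    continue
                ok &= np.sum((pts - coords[j]) ** 2, axis=1) > ext[j] ** 2
            area_acc += band_area * ok.sum() / n_phi
        total[i] = area_acc
    return total


def brute_force_signature(atoms, d_min, d_max, step):
    """Nested-loop recount of cumulative pharmacophore-pair shell counts."""
    n_shells = int(np.floor((d_max - d_min) / step + 1e-9)) + 1
    cutoffs = [d_min + k * step for k in range(n_shells)]
    cat_index = {pq: k for k, pq in enumerate(PAIR_CATEGORIES)}
    counts = np.zeros((n_shells, N_CATEGORIES), dtype=int)
    items = [(aa, a, sorted(atom_classes(aa, a.name))) for aa, a in atoms]
    for (aa1, a1, cls1), (aa2, a2, cls2) in combinations(items, 2):
        d = float(np.linalg.norm(a1.coord - a2.coord))
        for s, c in enumerate(cutoffs):
            if d <= c + 1e-9:
                for p in cls1:
                    for q in cls2:
                        i, j = sorted((CLASSES.index(p), CLASSES.index(q)))
                        counts[s, cat_index[(i, j)]] += 1
    return counts


def random_atom_panel(n, seed, spread=12.0):
    """Random coordinates carrying real residue/atom-name class labels."""
    rng = np.random.default_rng(seed)
    named = [("D", "OD1"), ("K", "NZ"), ("F", "CZ"), ("C", "SG"), ("S", "OG"),
             ("A", "CB"), ("G", "CA"), ("H", "ND1"), ("W", "NE1"), ("E", "CD"),
             ("A", "N"), ("A", "O")]
    atoms = []
    for _i in range(n):
        aa, name = named[int(rng.integers(len(named)))]
        coord = rng.uniform(0, spread, size=3)
        atoms.append((aa, Atom(name, name[0], coord)))
    return atoms
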