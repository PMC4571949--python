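"""Synthetic inputs with the structure the analysis stages assume.

Four generators, all pure functions of their parameters and a seed:

* dual-peak spectral-sensitivity spectra — a dominant Gaussian UV band
  (the sensitizing pigment) plus a log-normal visible α-band, with
  optional additive Gaussian noise;
* rhodopsin/metarhodopsin difference spectra from the two-template model;
* protein alignments evolved on a known tree under an equal-rates
  (Jukes–Cantor-style, 20-letter) replacement process;
* toy PDB coordinate sets with a lysine-bound chromophore and residues
  placed at constructed distances, for the pocket-geometry stage.

The sensitizing-pigment band is modeled as a Gaussian because only the
presence of a dominant UV peak matters for exercising the fitting-window
logic; its true shape is not part of the model being tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import biotite.structure as struc
import dendropy
import numpy as np

from .msp import build_difference
from .phylogeny import PROTEIN_ALPHABET, Alignment
from .spectra import Spectrum, SpectrumKind
from .templates import TemplateParams, alpha_band

__all__ = [
    "SensitivitySimSpec",
    "simulate_sensitivity",
    "simulate_difference",
    "simulate_alignment",
    "toy_structure",
    "expected_p_distance",
]


@dataclass(frozen=True)
class SensitivitySimSpec:
    """Parameters of one synthetic fly-photoreceptor sensitivity spectrum.

    Defaults place the sensitizing-pigment band at 350 nm with twice the
    α-band's peak amplitude, mimicking the dominant UV peak of R1–6
    recordings.
    """

    lambda_max_R: float
    uv_peak_center: float = 350.0
    uv_peak_width: float = 25.0
    uv_to_visible_ratio: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uv_peak_width <= 0:
            raise ValueError("uv_peak_width must be > 0")
        if self.uv_to_visible_ratio < 0:
            raise ValueError("uv_to_visible_ratio must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def simulate_sensitivity(
    spec: SensitivitySimSpec, grid, params: TemplateParams | None = None
) -> Spectrum:
    """Dual-peak sensitivity spectrum: UV Gaussian + α-band + noise, clipped at 0."""
    grid = np.asarray(grid, dtype=float)
    tp = (
        TemplateParams(spec.lambda_max_R)
        if params is None
        else TemplateParams(spec.lambda_max_R, dict(params.shape_coefficients))
    )
    uv = spec.uv_to_visible_ratio * np.exp(
        -0.5 * ((grid - spec.uv_peak_center) / spec.uv_peak_width) ** 2
    )
    vals = uv + alpha_band(grid, tp)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sigma, size=grid.size)
    return Spectrum(
        grid,
        np.clip(vals, 0.0, None),
        SpectrumKind.SENSITIVITY,
        label=f"sim sensitivity λmaxR={spec.lambda_max_R:g}",
    )


def simulate_difference(
    lambda_max_R: float,
    lambda_max_M: float,
    amplitude_R: float,
    amplitude_M: float,
    noise_sigma: float,
    seed: int,
    grid,
    params: TemplateParams | None = None,
) -> Spectrum:
    """Model difference spectrum plus additive Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    ds = build_difference(lambda_max_R, lambda_max_M, amplitude_R, amplitude_M, grid, params)
    vals = ds.values
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sigma, size=vals.size)
    return Spectrum(ds.wavelengths, vals, SpectrumKind.DIFFERENCE, label="sim difference")


# ---------------------------------------------------------------------------
# sequence evolution


def expected_p_distance(divergence: float) -> float:
    """Closed-form expected p-distance at total path length ``divergence``
    under the 20-state equal-rates replacement process.

    Substitution events arrive as a Poisson process (rate 1 per unit
    branch length per site); each event replaces the residue with one of
    the other 19 uniformly.  P(identical) = 1/20 + (19/20)·exp(−20d/19).
    """
    return 1.0 - (1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * divergence / 19.0))


def simulate_alignment(tree: dendropy.Tree, length: int, seed: int = 0) -> Alignment:
    """Evolve an alignment of ``length`` columns down ``tree``.

    The root sequence is uniform over the 20 amino-acid alphabet; along
    each branch every site receives a Poisson(branch length) number of
    substitution events, each replacing the residue with one of the other
    19 letters uniformly (equal-rates model).  Branch lengths are
    expected substitutions per site.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(PROTEIN_ALPHABET))
    k = len(letters)
    root_seq = rng.integers(0, k, size=length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    names, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = seqs[id(node)]
        else:
            bl = node.edge.length or 0.0
            if bl < 0:
                raise ValueError("branch lengths must be >= 0")
            seq = seqs[id(node.parent_node)].copy()
            counts = rng.poisson(bl, size=length)
            for site in np.nonzero(counts)[0]:
                for _ in range(counts[site]):
                    # jump to one of the other k-1 letters, uniformly
                    step = rng.integers(1, k)
                    seq[site] = (seq[site] + step) % k
            seqs[id(node)] = seq
        if node.is_leaf():
            names.append(node.taxon.label if node.taxon else f"leaf{len(names)}")
            rows.append("".join(letters[seq]))
    return Alignment(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# toy coordinates


#: residue -> side-chain oxygen atom placed by the toy generator
_SIDECHAIN_O = {
    "ASP": "OD1",
    "GLU": "OE1",
    "ASN": "OD1",
    "GLN": "OE1",
    "SER": "OG",
    "THR": "OG1",
    "TYR": "OH",
}


def _directions(n: int) -> np.ndarray:
    """n well-spread unit vectors on the upper hemisphere.

    The chromophore stub extends along −z, so placing residues at z ≥ 0
    guarantees each residue's closest chromophore atom is the Schiff-base
    nitrogen at the origin — the constructed distance is exact.
    """
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - i / n)  # polar angle in [0, 90°]
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def toy_structure(
    residues: list[tuple[str, int, float]],
    chromophore_name: str = "LYR",
    chromophore_id: int = 319,
    nitrogen_atom: str = "NZ",
) -> struc.AtomArray:
    """Minimal coordinate set: a chromophore plus residues at set distances.

    ``residues`` lists ``(residue name, residue number, distance)``; each
    residue's side-chain oxygen (per standard PDB naming) is placed
    exactly ``distance`` Å from the chromophore's Schiff-base nitrogen,
    with CB/CA atoms 1.5/2.9 Å further out along the same direction.
    Residues without a side-chain oxygen (e.g. GLY) get only CA/CB atoms,
    the CA at the stated distance.
    """
    atoms: list[tuple[str, str, int, bool, str, np.ndarray]] = []
    # chromophore: Schiff-base nitrogen at the origin, short polyene stub
    axis = np.array([0.0, 0.0, -1.0])
    for name, elem, dist in [("NZ", "N", 0.0), ("CE", "C", 1.5), ("CD", "C", 2.9), ("C15", "C", 4.2)]:
        aname = nitrogen_atom if name == "NZ" else name
        atoms.append((aname, elem, chromophore_id, True, chromophore_name, dist * axis))
    dirs = _directions(max(len(residues), 2))
    for (resname, resid, dist), u in zip(residues, dirs):
        o_name = _SIDECHAIN_O.get(resname.upper())
        if o_name is not None:
            atoms.append((o_name, "O", resid, False, resname.upper(), dist * u))
            atoms.append(("CB", "C", resid, False, resname.upper(), (dist + 1.5) * u))
            atoms.append(("CA", "C", resid, False, resname.upper(), (dist + 2.9) * u))
        else:
            atoms.append(("CA", "C", resid, False, resname.upper(), dist * u))
            atoms.append(("CB", "C", resid, False, resname.upper(), (dist + 1.5) * u))
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a[5] for a in atoms])
    arr.atom_name = np.array([a[0] for a in atoms])
    arr.element = np.array([a[1] for a in atoms])
    arr.res_id = np.array([a[2] for a in atoms])
    arr.hetero = np.array([a[3] for a in atoms])
    arr.res_name = np.array([a[4] for a in atoms])
    arr.chain_id = np.full(len(atoms), "A")
    return arr
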