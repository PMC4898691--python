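"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulating the experiments the pipeline analyzes: Beer-Lambert
spectral mixtures of the flavin redox ladder plus the thionine reporter dye,
Nernstian electron partitioning during a dye-equilibrium titration,
pseudo-first-order stopped-flow reoxidation traces, sequence families carrying
the per-type diagnostic residues, alignments evolved on known trees, and toy
isoalloxazine coordinate sets with a controllable butterfly bend.  Every
generator is seeded and returns the ground truth it used, so each estimator
can be tested as a round trip.

Defaults follow the study conditions: 15 uM enzyme and dye, thionine E0 =
+64 mV, enzyme E0 = +61 mV, k2 = 3040 M^-1 s^-1, dissolved O2 after 1:1
mixing with air-saturated buffer 1.29e-4 M (half of 2.58e-4 M at 25 degC),
additive Gaussian noise of 0.002 AU.  The extinction band shapes are
Gaussians with package-chosen (non-measured) parameters that qualitatively
reproduce the flavin/thionine spectra; all are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

from . import activesite
from .kinetics import KineticTrace
from .redox import RedoxCouple, partition_electrons
from .spectra import BasisSet, SpectralSeries
from .structgeom import AtomRecord, StructureModel

__all__ = [
    "SpeciesBandModel",
    "GeneratorConfig",
    "GroundTruth",
    "DEFAULT_BAND_MODELS",
    "DEFAULT_O2_CONC_M",
    "default_basis",
    "make_basis",
    "simulate_photoreduction",
    "photoreduction_fractions",
    "simulate_dye_equilibrium",
    "simulate_stopped_flow",
    "make_sequence_family",
    "evolve_alignment",
    "make_toy_isoalloxazine",
]

VALID_SPECIES = ("flavin_ox", "flavin_asq", "flavin_red", "dye_ox", "dye_red")

#: Dissolved O2 after 1:1 stopped-flow mixing of anaerobic enzyme with
#: air-saturated buffer at 25 degC (half of 2.58e-4 M air saturation).
DEFAULT_O2_CONC_M = 1.29e-4


@dataclass(frozen=True)
class SpeciesBandModel:
    """Gaussian extinction bands (center nm, width nm, peak M^-1 cm^-1) of one species."""

    species_id: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.species_id not in VALID_SPECIES:
            raise ValueError(f"unknown species {self.species_id!r}")
        bands = tuple(tuple(map(float, b)) for b in self.bands)
        for center, width, peak in bands:
            if width <= 0:
                raise ValueError("band widths must be positive")
            if peak < 0:
                raise ValueError("extinctions must be nonnegative")
        if self.species_id == "flavin_ox" and not any(
                440.0 <= c <= 460.0 for c, _, _ in bands):
            raise ValueError("flavin_ox needs a band centered in 440-460 nm")
        if self.species_id == "flavin_asq" and not any(
                360.0 <= c <= 400.0 for c, _, _ in bands):
            raise ValueError("flavin_asq needs a band centered in 360-400 nm")
        object.__setattr__(self, "bands", bands)

    def extinction(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(wl)
        for center, width, peak in self.bands:
            out += peak * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out


#: Default band models (package choices, not measured values): oxidized flavin
#: with its 375/450-nm double band, the anionic semiquinone's 380-nm rise,
#: weak reduced-flavin UV absorbance, oxidized thionine at 600 nm and a
#: colorless leuco dye.
DEFAULT_BAND_MODELS: tuple[SpeciesBandModel, ...] = (
    SpeciesBandModel("flavin_ox", ((375.0, 25.0, 9500.0), (450.0, 28.0, 11300.0))),
    SpeciesBandModel("flavin_asq", ((380.0, 30.0, 22000.0),)),
    SpeciesBandModel("flavin_red", ((345.0, 30.0, 4500.0),)),
    SpeciesBandModel("dye_ox", ((600.0, 35.0, 56000.0),)),
    SpeciesBandModel("dye_red", ()),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared experiment geometry, concentrations, noise and seed."""

    wavelength_grid: np.ndarray = None
    path_length_cm: float = 1.0
    enzyme_conc_M: float = 15e-6
    dye_conc_M: float = 15e-6
    noise_sd_AU: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        grid = self.wavelength_grid
        if grid is None:
            grid = np.arange(300.0, 701.0, 1.0)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0 or not np.all(np.diff(grid) > 0):
            raise ValueError("wavelength grid must be nonempty and strictly increasing")
        if self.enzyme_conc_M < 0 or self.dye_conc_M < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.noise_sd_AU < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "wavelength_grid", grid)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used: recovery-test bookkeeping."""

    fractions: pd.DataFrame | None = None
    E0_enzyme_mV: float | None = None
    E0_dye_mV: float | None = None
    k2_per_M_per_s: float | None = None
    k_obs_per_s: float | None = None
    tree_newick: str | None = None
    type_label: str | None = None
    template: str | None = None


def make_basis(models: Sequence[SpeciesBandModel],
               grid: np.ndarray,
               path_length_cm: float = 1.0) -> BasisSet:
    """Evaluate Gaussian band models on a wavelength grid into a BasisSet."""
    if len(models) == 0:
        raise ValueError("need at least one species model")
    ids = [m.species_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    ext = np.vstack([m.extinction(grid) for m in models])
    return BasisSet(tuple(ids), grid, ext, path_length_cm)


def default_basis(config: GeneratorConfig | None = None) -> BasisSet:
    config = config or GeneratorConfig()
    return make_basis(DEFAULT_BAND_MODELS, config.wavelength_grid,
                      config.path_length_cm)


# ---------------------------------------------------------------------------
# photoreduction (ox <-> asq <-> red ladder)
# ---------------------------------------------------------------------------

def photoreduction_fractions(dose_equiv: float, semiquinone_K: float
                             ) -> tuple[float, float, float]:
    """(f_ox, f_sq, f_red) of the two-step one-electron ladder at a given dose.

    ``dose_equiv`` is the cumulative electron dose in equivalents per flavin
    (0..2); ``semiquinone_K`` is the semiquinone stability constant
    K = [sq]^2 / ([ox][red]) of the disproportionation equilibrium.  Solved by
    bracketed root-finding on the fully-reduced fraction.
    """
    if not (0.0 <= dose_equiv <= 2.0):
        raise ValueError("dose must be in [0, 2] equivalents")
    if semiquinone_K < 0:
        raise ValueError("K must be nonnegative")
    d = float(dose_equiv)
    if d == 0.0:
        return 1.0, 0.0, 0.0
    if d == 2.0:
        return 0.0, 0.0, 1.0

    def imbalance(r: float) -> float:
        f_sq = d - 2.0 * r
        f_ox = 1.0 - d + r
        return f_sq * f_sq - semiquinone_K * f_ox * r

    r_lo = max(0.0, d - 1.0)
    r_hi = d / 2.0
    if imbalance(r_lo) <= 0:          # K = inf limit cannot occur; K = 0 edge
        r = r_lo
    else:
        r = brentq(imbalance, r_lo, r_hi, xtol=1e-15)
    f_red = float(r)
    f_sq = float(d - 2.0 * r)
    f_ox = float(1.0 - d + r)
    return f_ox, f_sq, f_red


def simulate_photoreduction(config: GeneratorConfig, basis: BasisSet,
                            semiquinone_K: float = 25.0,
                            n_steps: int = 20) -> tuple[SpectralSeries, GroundTruth]:
    """Stepwise photoreduction: dose ramps 0 -> 2 equivalents over n_steps.

    The anionic semiquinone rises (380-nm band) and decays as the enzyme
    passes through one-electron reduction; spectra are the Beer-Lambert
    forward model plus i.i.d. Gaussian noise.
    """
    if n_steps < 3:
        raise ValueError("need at least 3 steps")
    for sp in ("flavin_ox", "flavin_asq", "flavin_red"):
        if sp not in basis.species_ids:
            raise ValueError(f"basis lacks flavin species {sp!r}")
    rng = np.random.default_rng(config.seed)
    doses = np.linspace(0.0, 2.0, n_steps)
    rows, spectra = [], []
    for step, d in enumerate(doses):
        f_ox, f_sq, f_red = photoreduction_fractions(d, semiquinone_K)
        conc = {"flavin_ox": config.enzyme_conc_M * f_ox,
                "flavin_asq": config.enzyme_conc_M * f_sq,
                "flavin_red": config.enzyme_conc_M * f_red}
        clean = basis.absorbance(conc)
        spectra.append(clean + rng.normal(0.0, config.noise_sd_AU, clean.size))
        rows.append({"stamp": float(step), "dose_equiv": float(d),
                     "f_ox": f_ox, "f_sq": f_sq, "f_red": f_red})
    series = SpectralSeries(np.arange(n_steps, dtype=float),
                            basis.wavelengths_nm, np.vstack(spectra))
    return series, GroundTruth(fractions=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# dye-equilibrium titration
# ---------------------------------------------------------------------------

def simulate_dye_equilibrium(config: GeneratorConfig, basis: BasisSet,
                             E0_enz_mV: float = 61.0,
                             E0_dye_mV: float = 64.0,
                             dose_schedule: Sequence[float] | None = None,
                             n_enzyme: int = 2, n_dye: int = 2
                             ) -> tuple[SpectralSeries, GroundTruth]:
    """Simultaneous reduction of enzyme and reporter dye at mutual equilibrium.

    At each cumulative electron dose (M of electrons) the reduced equivalents
    are partitioned so both couples sit at one solution potential
    (:func:`bbekit.redox.partition_electrons`).  Both pools are treated as
    2-electron ox/red couples; no semiquinone is populated here.  The default
    schedule is 30 even steps from zero to full capacity.
    """
    for sp in ("flavin_ox", "flavin_red", "dye_ox", "dye_red"):
        if sp not in basis.species_ids:
            raise ValueError(f"basis lacks species {sp!r}")
    enzyme = RedoxCouple(E0_enz_mV, n_enzyme, config.enzyme_conc_M)
    dye = RedoxCouple(E0_dye_mV, n_dye, config.dye_conc_M)
    capacity = n_enzyme * config.enzyme_conc_M + n_dye * config.dye_conc_M
    if dose_schedule is None:
        dose_schedule = np.linspace(0.0, capacity, 30)
    doses = np.asarray(dose_schedule, dtype=float)
    if np.any(np.diff(doses) < 0):
        raise ValueError("dose schedule must be nondecreasing")
    if doses.size and doses[-1] > capacity * (1 + 1e-12):
        raise ValueError(f"final dose {doses[-1]} exceeds capacity {capacity}")
    rng = np.random.default_rng(config.seed)
    rows, spectra = [], []
    for step, dose in enumerate(doses):
        f_e, f_d, e_sol = partition_electrons(min(dose, capacity), enzyme, dye)
        conc = {"flavin_ox": config.enzyme_conc_M * (1 - f_e),
                "flavin_red": config.enzyme_conc_M * f_e,
                "dye_ox": config.dye_conc_M * (1 - f_d),
                "dye_red": config.dye_conc_M * f_d}
        clean = basis.absorbance(conc)
        spectra.append(clean + rng.normal(0.0, config.noise_sd_AU, clean.size))
        rows.append({"stamp": float(step), "dose_equiv_M": float(dose),
                     "f_red_enzyme": f_e, "f_red_dye": f_d,
                     "E_solution_mV": e_sol})
    series = SpectralSeries(np.arange(doses.size, dtype=float),
                            basis.wavelengths_nm, np.vstack(spectra))
    truth = GroundTruth(fractions=pd.DataFrame(rows),
                        E0_enzyme_mV=E0_enz_mV, E0_dye_mV=E0_dye_mV)
    return series, truth


# ---------------------------------------------------------------------------
# stopped-flow reoxidation
# ---------------------------------------------------------------------------

def simulate_stopped_flow(config: GeneratorConfig, basis: BasisSet,
                          k2_per_M_per_s: float = 3040.0,
                          O2_conc_M: float = DEFAULT_O2_CONC_M,
                          t_grid: Sequence[float] | None = None
                          ) -> tuple[KineticTrace, GroundTruth]:
    """Pseudo-first-order reoxidation of reduced enzyme followed at 450 nm.

    A450(t) = A_inf - dA * exp(-k2*[O2]*t) + noise, with A_inf and dA from the
    oxidized/reduced flavin extinctions at 450 nm.  Warns when [O2] is less
    than 5x the enzyme concentration (pseudo-first-order assumption strained).
    """
    if k2_per_M_per_s <= 0 or O2_conc_M <= 0:
        raise ValueError("k2 and [O2] must be positive")
    if O2_conc_M < 5.0 * config.enzyme_conc_M:
        warnings.warn("[O2] < 5x enzyme: pseudo-first-order assumption strained")
    k_obs = k2_per_M_per_s * O2_conc_M
    if t_grid is None:
        t_grid = np.linspace(0.0, 6.0 / k_obs, 300)
    t = np.asarray(t_grid, dtype=float)
    path = basis.path_length_cm
    wl450 = 450.0
    ext_ox = float(np.interp(wl450, basis.wavelengths_nm, basis.column("flavin_ox")))
    ext_red = float(np.interp(wl450, basis.wavelengths_nm, basis.column("flavin_red")))
    a_inf = path * config.enzyme_conc_M * ext_ox
    a0 = path * config.enzyme_conc_M * ext_red
    delta_a = a_inf - a0
    rng = np.random.default_rng(config.seed)
    a = a_inf - delta_a * np.exp(-k_obs * t) + rng.normal(0.0, config.noise_sd_AU, t.size)
    truth = GroundTruth(k2_per_M_per_s=float(k2_per_M_per_s),
                        k_obs_per_s=float(k_obs))
    return KineticTrace(t, a), truth


# ---------------------------------------------------------------------------
# sequences, alignments, trees
# ---------------------------------------------------------------------------

def make_sequence_family(type_label: str, n_seqs: int = 20,
                         mutation_rate: float = 0.02,
                         seed: int = 0) -> tuple[list[SeqRecord], GroundTruth]:
    """A protein family of one active-site type with preserved diagnostics.

    Every member carries the type's diagnostic residues (and the GGHD
    attachment context) at the literal reference positions; all other
    positions mutate independently at ``mutation_rate`` to a random different
    amino acid.
    """
    template = activesite.type_template(type_label)
    protected = set(activesite.TYPE_TEMPLATE_RESIDUES[type_label]) | {109, 110, 111, 112}
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(activesite.AA_ALPHABET))
    records = []
    for i in range(n_seqs):
        seq = list(template)
        for pos in range(1, len(seq) + 1):
            if pos in protected:
                continue
            if rng.random() < mutation_rate:
                choices = alphabet[alphabet != seq[pos - 1]]
                seq[pos - 1] = str(rng.choice(choices))
        records.append(SeqRecord(Seq("".join(seq)),
                                 id=f"{type_label}_member_{i:03d}",
                                 description=f"synthetic type {type_label} family member"))
    return records, GroundTruth(type_label=type_label, template=template)


def evolve_alignment(tree_newick: str, seq_length: int = 500,
                     subst_prob_per_branch: float = 0.05,
                     seed: int = 0):
    """Evolve an ungapped protein alignment down a tree with branch lengths.

    ``subst_prob_per_branch`` is the per-site substitution probability on a
    branch of unit length; a branch of length L substitutes each site with
    probability 1 - (1 - p)**L (so expected pairwise differences grow with
    path length).  Substitutions draw uniformly from the 19 other residues.
    Returns (:class:`bbekit.phylo.MSA`, GroundTruth with the input newick).
    """
    import dendropy

    from .phylo import MSA

    if not (0.0 <= subst_prob_per_branch < 1.0):
        raise ValueError("substitution probability must be in [0, 1)")
    try:
        tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(activesite.AA_ALPHABET))
    root_seq = rng.choice(alphabet, size=seq_length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    ids, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        length = node.edge.length or 0.0
        p = 1.0 - (1.0 - subst_prob_per_branch) ** length
        seq = parent_seq.copy()
        hits = np.nonzero(rng.random(seq_length) < p)[0]
        for j in hits:
            choices = alphabet[alphabet != seq[j]]
            seq[j] = rng.choice(choices)
        seqs[id(node)] = seq
        if node.is_leaf():
            ids.append(node.taxon.label.replace(" ", "_"))
            rows.append("".join(seq))
    return MSA(tuple(ids), tuple(rows)), GroundTruth(tree_newick=tree_newick)


# ---------------------------------------------------------------------------
# toy isoalloxazine coordinates
# ---------------------------------------------------------------------------

def make_toy_isoalloxazine(bend_deg: float,
                           chloride_distance_A: float = 3.1) -> StructureModel:
    """Idealized three-ring flavin hinged about N5-N10 plus a chloride at C4a.

    The tricycle is built from regular hexagons (bond 1.4 A) in the z = 0
    plane with the N5-N10 hinge on the x axis; the dimethylbenzene wing is
    rotated by ``bend_deg`` about that axis, so the inter-ring plane angle
    equals the requested bend exactly.  The chloride sits ``chloride_distance_A``
    above C4X along z.
    """
    if not (0.0 <= bend_deg <= 45.0):
        raise ValueError("bend must be in [0, 45] degrees")
    if chloride_distance_A <= 0:
        raise ValueError("chloride distance must be positive")
    s3 = 1.4 * np.sqrt(3.0) / 2.0  # hexagon half-height for bond length 1.4
    # middle (pyrazine) ring: N5 and N10 para on the x axis
    middle = {"N5": (1.4, 0.0), "C4X": (0.7, s3), "C10": (-0.7, s3),
              "N10": (-1.4, 0.0), "C9A": (-0.7, -s3), "C5X": (0.7, -s3)}
    pyrimidine = {"C4": (1.4, 2 * s3), "N3": (0.7, 3 * s3),
                  "C2": (-0.7, 3 * s3), "N1": (-1.4, 2 * s3)}
    benzene = {"C6": (1.4, -2 * s3), "C7": (0.7, -3 * s3),
               "C8": (-0.7, -3 * s3), "C9": (-1.4, -2 * s3)}
    theta = np.radians(bend_deg)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, np.cos(theta), -np.sin(theta)],
                      [0.0, np.sin(theta), np.cos(theta)]])
    atoms = []

    def add(name: str, xy: tuple[float, float], wing: bool, element: str = "C") -> None:
        xyz = np.array([xy[0], xy[1], 0.0])
        if wing:
            xyz = rot_x @ xyz
        atoms.append(AtomRecord(name, "FAD", 1, "A", element, xyz, is_hetatm=True))

    for name, xy in middle.items():
        # benzene wing carries its shared junction atoms C5X/C9A
        add(name, xy, wing=name in ("C5X", "C9A"),
            element="N" if name.startswith("N") else "C")
    for name, xy in pyrimidine.items():
        add(name, xy, wing=False, element="N" if name.startswith("N") else "C")
    for name, xy in benzene.items():
        add(name, xy, wing=True)
    c4x = np.array([0.7, s3, 0.0])
    atoms.append(AtomRecord("CL", "CL", 2, "A", "Cl",
                            c4x + np.array([0.0, 0.0, chloride_distance_A]),
                            is_hetatm=True))
    return StructureModel(atoms)
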