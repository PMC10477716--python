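"""Synthetic datasets with the statistical structure the analysis assumes.

Three generators cover the three data streams of a fertilization-incubation
study (3 treatments x 8 replicate pots by default):

* :func:`gen_eem_dataset` — trilinear EEM fluorescence cubes built from a
  library of humic-like components (default peaks ex/em 280/401, 355/443,
  275/468 nm) plus Rayleigh/Raman scatter ridges and Gaussian noise, with a
  matching blank;
* :func:`gen_community` — OTU count tables with planted correlation modules
  (a shared latent log-scale factor per module) and treatment-shifted taxa;
* :func:`gen_mineralization` — alkali-trap titration records consistent with
  a decaying daily CO2 emission curve on the 1/3/5/7/10/15/20/25/30-day
  sampling schedule.

Every generator records its exact ground truth in a :class:`SynthTruth` so
downstream stages can be validated against known parameters. Outputs are
bit-reproducible for a fixed (design, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mineralization as mz
from ._utils import gaussian_profile
from .community import OTUTable, TAXONOMY_RANKS
from .eem import EX_GRID, EM_GRID, EEMCube


@dataclass
class ComponentSpec:
    """One fluorophore: Gaussian excitation/emission peaks on the lattice."""

    ex_peak: float
    em_peak: float
    ex_width: float = 25.0
    em_width: float = 35.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.em_peak <= self.ex_peak:
            raise ValueError(
                f"{self.label or 'component'}: em_peak must exceed ex_peak (Stokes shift)"
            )
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ValueError("widths must be positive")
        if not (200 <= self.ex_peak <= 450) or not (250 <= self.em_peak <= 600):
            raise ValueError(
                f"{self.label or 'component'}: peak outside instrument range"
            )


def default_components() -> list[ComponentSpec]:
    """The default three humic-like components.

    C1 280/401 nm (microbial humic acid-like), C2 355/443 nm and C3
    275/468 nm (terrestrial humic acid-like).
    """
    return [
        ComponentSpec(280, 401, label="C1 microbial humic acid-like"),
        ComponentSpec(355, 443, label="C2 terrestrial humic acid-like"),
        ComponentSpec(275, 468, label="C3 terrestrial humic acid-like"),
    ]


def _default_score_effects() -> dict[str, tuple[float, ...]]:
    # Treatment x component intensity multipliers: green-manure + biochar
    # boosts the microbial humic-like component and depresses C3.
    return {"NPK": (1.0, 1.0, 1.0), "GM": (1.1, 1.05, 0.95), "GMC": (1.35, 1.0, 0.7)}


@dataclass
class SynthDesign:
    """Design of the synthetic study (treatments, replicates, noise, taxa)."""

    treatments: tuple[str, ...] = ("NPK", "GM", "GMC")
    replicates_per_treatment: int = 8
    seed: int = 0
    # EEM stream -------------------------------------------------------
    noise_sd: float | None = None  # absolute Gaussian noise sd; overrides frac
    noise_frac: float = 0.005  # noise sd as a fraction of the noiseless max
    score_base: float = 10.0  # median component intensity (arbitrary units)
    score_sigma: float = 0.3  # log-sd of sample-to-sample score variation
    score_effects: dict = field(default_factory=_default_score_effects)
    # Community stream -------------------------------------------------
    n_taxa: int = 300
    n_modules: int = 4
    module_size: int = 30
    module_weight: float = 3.0  # latent-factor weight -> within-module rho ~ 0.8
    taxon_noise_sd: float = 1.0  # log-scale idiosyncratic noise
    base_abundance_log_mean: float = 5.5
    base_abundance_log_sd: float = 0.8
    zero_inflation: float = 0.02
    effect_taxa: tuple | None = None  # default: the first planted module
    treatment_effect: dict = field(
        default_factory=lambda: {"NPK": 1.0, "GM": 1.3, "GMC": 1.6}
    )
    # treatment -> planted modules absent from that treatment's samples.
    # Silencing a different module per less-amended treatment keeps every
    # module above the global prevalence cutoff while making the
    # co-incorporation treatment's subnetwork the most complex.
    silenced_modules: dict = field(
        default_factory=lambda: {"NPK": [3], "GM": [4]}
    )

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 2:
            raise ValueError("need >= 2 replicates per treatment")
        if self.n_modules * self.module_size > self.n_taxa:
            raise ValueError("n_modules * module_size exceeds n_taxa")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must be a probability")
        for t in self.treatments:
            if t not in self.score_effects:
                raise ValueError(f"no score_effects entry for treatment {t}")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{t}_r{i + 1}"
            for t in self.treatments
            for i in range(self.replicates_per_treatment)
        ]

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * self.replicates_per_treatment

    def metadata(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{t}_r{i + 1}", "treatment": t, "replicate": i + 1}
            for t in self.treatments
            for i in range(self.replicates_per_treatment)
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class SynthTruth:
    """Exact generating parameters recorded alongside synthetic data."""

    true_ex_loadings: pd.DataFrame | None = None  # wavelength x component, unit norm
    true_em_loadings: pd.DataFrame | None = None
    true_scores: pd.DataFrame | None = None  # sample x component
    module_assignment: dict | None = None  # taxon -> module id or "background"
    driver_coefficients: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "driver_coefficients": self.driver_coefficients,
            "extras": self.extras,
        }
        if self.true_scores is not None:
            payload["true_scores"] = self.true_scores.to_dict()
        if self.module_assignment is not None:
            payload["module_assignment"] = self.module_assignment
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


# --------------------------------------------------------------------- EEMs


def _scatter_background(
    ex_grid: np.ndarray, em_grid: np.ndarray, scale: float
) -> np.ndarray:
    """Rayleigh ridges (em ~ ex and em ~ 2 ex) plus the water Raman band.

    The same background is present in blanks and samples, so blank
    subtraction cancels it exactly up to excision of the residual bands.
    """
    em = em_grid[:, None]
    ex = ex_grid[None, :]
    first = 2.0 * scale * np.exp(-0.5 * ((em - ex) / 4.0) ** 2)
    second = 0.5 * scale * np.exp(-0.5 * ((em - 2.0 * ex) / 4.0) ** 2)
    # Water Raman: ~3400 cm^-1 shift from the excitation line.
    with np.errstate(divide="ignore"):
        raman_em = 1.0 / (1.0 / ex - 3.4e-4)
    raman = 0.3 * scale * np.exp(-0.5 * ((em - raman_em) / 8.0) ** 2)
    return first + second + raman


def gen_eem_dataset(
    design: SynthDesign, components: list[ComponentSpec] | None = None
) -> tuple[EEMCube, EEMCube, SynthTruth]:
    """Generate sample EEMs, a matching blank, and the generating truth.

    Each sample EEM is the trilinear sum over components of
    score * ex_loading * em_loading, plus the shared scatter background and
    Gaussian noise. Component peaks must sit on the instrument lattice
    (ex 200-450 step 5, em 250-600 step 1).
    """
    if components is None:
        components = default_components()
    if not components:
        raise ValueError("need at least one component")
    for c in components:
        if not np.isclose(EX_GRID, c.ex_peak).any():
            raise ValueError(
                f"ex peak {c.ex_peak} nm of {c.label or 'component'} is off the 5-nm lattice"
            )
        if not np.isclose(EM_GRID, c.em_peak).any():
            raise ValueError(
                f"em peak {c.em_peak} nm of {c.label or 'component'} is off the 1-nm lattice"
            )

    rng = np.random.default_rng(design.seed)
    R = len(components)
    ex_load = np.column_stack([gaussian_profile(EX_GRID, c.ex_peak, c.ex_width) for c in components])
    em_load = np.column_stack([gaussian_profile(EM_GRID, c.em_peak, c.em_width) for c in components])

    sample_ids = design.sample_ids
    scores = np.empty((design.n_samples, R))
    for i, sid in enumerate(sample_ids):
        treatment = sid.rsplit("_r", 1)[0]
        mult = np.asarray(design.score_effects[treatment][:R], dtype=float)
        scores[i] = (
            design.score_base
            * mult
            * rng.lognormal(mean=0.0, sigma=design.score_sigma, size=R)
        )

    signal = np.einsum("ir,jr,kr->ijk", scores, em_load, ex_load)
    smax = float(signal.max())
    noise_sd = design.noise_sd if design.noise_sd is not None else design.noise_frac * smax

    background = _scatter_background(EX_GRID, EM_GRID, scale=smax)
    noisy = signal + background[None] + rng.normal(0.0, noise_sd, size=signal.shape)
    noisy = np.clip(noisy, 0.0, None)

    cube = EEMCube(
        sample_ids=sample_ids,
        ex_grid=EX_GRID.copy(),
        em_grid=EM_GRID.copy(),
        intensities=noisy,
    )
    blank = EEMCube(
        sample_ids=["blank"],
        ex_grid=EX_GRID.copy(),
        em_grid=EM_GRID.copy(),
        intensities=background[None].copy(),
    )
    comp_names = [f"C{r + 1}" for r in range(R)]
    truth = SynthTruth(
        true_ex_loadings=pd.DataFrame(ex_load, index=EX_GRID, columns=comp_names),
        true_em_loadings=pd.DataFrame(em_load, index=EM_GRID, columns=comp_names),
        true_scores=pd.DataFrame(scores, index=sample_ids, columns=comp_names),
        extras={
            "noise_sd": noise_sd,
            "component_labels": [c.label for c in components],
            "signal_max": smax,
        },
    )
    return cube, blank, truth


def gen_noise_cube(
    n_samples: int = 24, seed: int = 0, scale: float = 1.0
) -> EEMCube:
    """A structureless corrected-format cube of half-normal noise.

    Synthetic null input for validation studies (e.g. split-half analysis on
    data with no trilinear structure).
    """
    rng = np.random.default_rng(seed)
    x = np.abs(rng.normal(0.0, scale, size=(n_samples, len(EM_GRID), len(EX_GRID))))
    return EEMCube(
        sample_ids=[f"noise_{i + 1}" for i in range(n_samples)],
        ex_grid=EX_GRID.copy(),
        em_grid=EM_GRID.copy(),
        intensities=x,
        corrected=True,
        provenance={"synthetic": "pure noise, no trilinear structure"},
    )


# ---------------------------------------------------------------- community


def _make_taxonomy(otu_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Random but hierarchy-consistent taxonomy labels down to genus."""
    n = len(otu_ids)
    genus = rng.integers(0, 40, size=n)
    family = genus // 2
    order = family // 2
    cls = order // 2
    phylum = cls // 2
    tax = pd.DataFrame(
        {
            "domain": ["Bacteria"] * n,
            "phylum": [f"Phylum_{i}" for i in phylum],
            "class": [f"Class_{i}" for i in cls],
            "order": [f"Order_{i}" for i in order],
            "family": [f"Family_{i}" for i in family],
            "genus": [f"Genus_{i}" for i in genus],
        },
        index=otu_ids,
    )
    return tax


def gen_community(design: SynthDesign) -> tuple[OTUTable, SynthTruth]:
    """Generate an OTU count table with planted correlation modules.

    Taxa in a planted module share a latent standard-normal factor added on
    the log-abundance scale with weight ``module_weight``, inducing positive
    Spearman correlation among members. Effect taxa are multiplied by
    treatment-specific factors; zero-inflation is applied before Poisson
    count draws. Modules listed in ``silenced_modules`` for a treatment have
    their member abundances set to zero in that treatment's samples.
    """
    if design.module_size < 2 and design.n_modules > 0:
        raise ValueError("module_size must be >= 2 (a module must be connectable)")
    rng = np.random.default_rng(design.seed)
    n, m = design.n_taxa, design.n_samples
    sample_ids = design.sample_ids
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]

    assignment: dict[str, object] = {}
    for i, oid in enumerate(otu_ids):
        mod = i // design.module_size + 1 if i < design.n_modules * design.module_size else "background"
        assignment[oid] = mod

    base = rng.lognormal(design.base_abundance_log_mean, design.base_abundance_log_sd, size=n)
    factors = rng.normal(size=(design.n_modules, m))  # latent module factor per sample
    noise = rng.normal(scale=design.taxon_noise_sd, size=(n, m))

    log_abund = np.log(base)[:, None] + noise
    for i, oid in enumerate(otu_ids):
        mod = assignment[oid]
        if mod != "background":
            log_abund[i] += design.module_weight * factors[mod - 1]

    effect_taxa = (
        tuple(design.effect_taxa)
        if design.effect_taxa is not None
        else tuple(otu_ids[: design.module_size])  # default: the first module
    )
    effect_idx = [otu_ids.index(t) for t in effect_taxa]
    treatments = np.array([s.rsplit("_r", 1)[0] for s in sample_ids])
    abund = np.exp(log_abund)
    for t, mult in design.treatment_effect.items():
        cols = treatments == t
        if cols.any() and effect_idx:
            abund[np.ix_(effect_idx, np.nonzero(cols)[0])] *= mult

    for t, mods in design.silenced_modules.items():
        cols = np.nonzero(treatments == t)[0]
        rows = [i for i, oid in enumerate(otu_ids) if assignment[oid] in mods]
        if len(cols) and rows:
            abund[np.ix_(rows, cols)] = 0.0

    keep = rng.random(size=abund.shape) >= design.zero_inflation
    counts = rng.poisson(abund * keep)

    # Guarantee positive column sums (an empty sample is not a valid library).
    for j in np.nonzero(counts.sum(axis=0) == 0)[0]:
        counts[int(rng.integers(0, n)), j] = 1

    table = OTUTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        taxonomy=_make_taxonomy(otu_ids, rng),
        metadata=design.metadata(),
    )
    truth = SynthTruth(
        module_assignment=assignment,
        driver_coefficients={"treatment_effect": dict(design.treatment_effect)},
        extras={
            "module_weight": design.module_weight,
            "effect_taxa": list(effect_taxa),
            "silenced_modules": {k: list(v) for k, v in design.silenced_modules.items()},
        },
    )
    return table, truth


# ----------------------------------------------------------- mineralization


def _default_base_rates() -> dict[str, float]:
    # Initial daily CO2-C emission (mg per kg soil per day) per treatment.
    # With the default 5%/day decay the discrete 30-day cumulative totals
    # are ~2592 / 2934 / 3434 mg/kg, the magnitudes reported for amended
    # paddy soils under mineral fertilizer, + green manure, + biochar.
    return {"NPK": 162.7, "GM": 184.2, "GMC": 215.6}


def gen_mineralization(
    design: SynthDesign,
    base_rates: dict[str, float] | None = None,
    decay: float = 0.05,
    titration_noise_mL: float = 0.05,
    n_blanks: int = 3,
    blank_co2_mg_per_day: float = 0.3,
    hcl_molarity: float = 0.4,
    naoh_molarity: float = 0.5,
    naoh_volume_mL: float = 20.0,
    soil_mass_kg: float = 0.030,
) -> tuple[mz.TitrationTable, SynthTruth]:
    """Generate alkali-trap titration records for a 30-day incubation.

    Daily emission for a jar of treatment T is
    ``base_rates[T] * exp(-decay * (day - 1))`` mg CO2-C per kg soil; the
    CO2 trapped between the scheduled openings (days 1,3,5,...,30) is
    converted (through the trap stoichiometry, inverse of
    :func:`soilcnet.mineralization.titration_to_co2`) to the HCl volume that
    a back-titration would measure. Blank jars trap only the background
    ``blank_co2_mg_per_day`` (absolute mg C per day).
    """
    if base_rates is None:
        base_rates = _default_base_rates()
    for t in design.treatments:
        if t not in base_rates:
            raise ValueError(f"no base rate for treatment {t}")
        if base_rates[t] < 0:
            raise ValueError("base rates must be non-negative")

    rng = np.random.default_rng(design.seed)
    naoh_mol = naoh_volume_mL / 1000.0 * naoh_molarity
    days = mz.SAMPLING_DAYS

    def interval_emission(base: float, day_from: int, day_to: int) -> float:
        ds = np.arange(day_from + 1, day_to + 1)
        return float(np.sum(base * np.exp(-decay * (ds - 1))))

    records = []
    true_cum: dict[str, float] = {}
    jar_meta = []
    for t in design.treatments:
        prev, cum = 0, 0.0
        for day in days:
            cum += interval_emission(base_rates[t], prev, day)
            prev = day
        true_cum[t] = cum

    for sid in design.sample_ids:
        t = sid.rsplit("_r", 1)[0]
        jar_meta.append({"jar": sid, "treatment": t})
        prev = 0
        for day in days:
            mg_per_kg = interval_emission(base_rates[t], prev, day)
            mg_c = mg_per_kg * soil_mass_kg + blank_co2_mg_per_day * (day - prev)
            mol_co2 = mg_c / 1000.0 / mz.CARBON_MOLAR_MASS
            residual = naoh_mol - 2.0 * mol_co2
            if residual <= 0:
                raise ValueError(
                    f"alkali trap capacity exceeded on day {day} for jar {sid}"
                )
            vol = residual / hcl_molarity * 1000.0
            if titration_noise_mL > 0:
                vol = max(0.0, vol + rng.normal(0.0, titration_noise_mL))
            records.append({"jar": sid, "day": day, "hcl_mL": vol, "is_blank": False})
            prev = day

    for b in range(n_blanks):
        jid = f"blank_{b + 1}"
        prev = 0
        for day in days:
            mg_c = blank_co2_mg_per_day * (day - prev)
            residual = naoh_mol - 2.0 * mg_c / 1000.0 / mz.CARBON_MOLAR_MASS
            vol = residual / hcl_molarity * 1000.0
            if titration_noise_mL > 0:
                vol = max(0.0, vol + rng.normal(0.0, titration_noise_mL))
            records.append({"jar": jid, "day": day, "hcl_mL": vol, "is_blank": True})
            prev = day

    table = mz.TitrationTable(
        records=pd.DataFrame(records),
        hcl_molarity=hcl_molarity,
        naoh_molarity=naoh_molarity,
        naoh_volume_mL=naoh_volume_mL,
        soil_mass_kg=soil_mass_kg,
        jar_metadata=pd.DataFrame(jar_meta),
    )
    truth = SynthTruth(
        driver_coefficients={"base_rates": dict(base_rates), "decay": decay},
        extras={"true_cum": true_cum, "blank_co2_mg_per_day": blank_co2_mg_per_day},
    )
    return table, truth
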