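"""A virtual ¹³C-straw incubation experiment with known ground truth.

The generator emulates the processed data tables of a labeled-straw soil
incubation: four treatments (an unamended control plus lignin-dominant,
mixed, and cellulose-dominant amendments) × two sampling days (7, 28) ×
three labeled and three unlabeled replicates for the isotope arm, six
replicates for the community arm.  Every stage of the analysis pipeline can
therefore be exercised as a parameter-recovery problem: the true straw-derived
fractions, the true carbon use efficiency, the planted community shifts and
the planted co-occurrence modules are all known by construction.

Forward model
-------------
*Isotope arm.*  Each treatment × timepoint cell has true straw-derived and
native amounts for the cumulative CO₂ and biomass pools.  Labeled-arm δ¹³C
values are drawn around the two-pool mixing line
``δ_soil + f·(δ_straw − δ_soil)`` with Gaussian noise on the ‰ scale;
unlabeled-arm δ values sit at the native endmember.  Pool sizes get
multiplicative log-normal noise with a stated CV (mean-preserving).  The
fumigated/non-fumigated extract pair is constructed by inverting the
fumigation mass balance, so the analysis recovers the intended biomass δ
exactly at zero noise.

*Community arm.*  ASV counts follow a log-normal relative-abundance model
with multinomial sampling: per-ASV baselines, per-phylum treatment effects
(log scale), a shared latent factor per planted module (so network recovery
is testable), and idiosyncratic noise, softmax-normalized and sampled at a
fixed library size.

All randomness derives from the design seed through named substreams, so a
seed fully determines every table and toggling one generator does not shift
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from strawcue.community import AsvTable
from strawcue.composition import CHEMICAL_GROUPS, SKELETON_CLASSES, OaComposition

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "CommunityTruth",
    "GeneTruth",
    "default_truth",
    "generate_isotope_samples",
    "generate_asv_tables",
    "generate_gene_abundances",
    "generate_oa_composition",
    "atom_fraction_to_delta",
]

#: ¹³C/¹²C ratio of the VPDB standard
R_VPDB = 0.0111802

# substream identifiers: child seeds are SeedSequence([seed, stream_id])
_STREAMS = {"isotope": 11, "bacterial": 12, "fungal": 13, "genes": 14}


def atom_fraction_to_delta(atom_fraction: float) -> float:
    """Convert a ¹³C atom fraction to a δ¹³C value (‰ vs VPDB)."""
    if not 0 < atom_fraction < 1:
        raise ValueError("atom fraction must be in (0, 1)")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / R_VPDB - 1.0) * 1000.0


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and labeling parameters of the incubation experiment.

    Defaults mirror the standard design: treatments Ctrl/LM/MM/CM, sampling
    at 7 and 28 days, 3 labeled + 3 unlabeled replicates for the isotope
    measurements, 6 replicates for community profiling, straw labeled at
    δ¹³C = 99‰ added at 1 mg straw-C g⁻¹ soil on top of amendments at
    5 mg C g⁻¹ soil, native soil baseline δ¹³C = −20‰ (typical C3 soil).
    """

    treatments: tuple[str, ...] = ("Ctrl", "LM", "MM", "CM")
    timepoints_days: tuple[int, ...] = (7, 28)
    n_reps_isotope: int = 3
    n_reps_community: int = 6
    delta_straw_permil: float = 99.0
    delta_soil_permil: float = -20.0
    straw_c_rate: float = 1.0  # mg straw-C g^-1 soil
    oa_c_rate: float = 5.0  # mg amendment-C g^-1 soil
    seed: int = 0
    atom_fraction_straw: float | None = None

    def __post_init__(self) -> None:
        if len(self.treatments) < 1 or len(self.timepoints_days) < 1:
            raise ValueError("need >=1 treatment and >=1 timepoint")
        if self.n_reps_isotope < 1 or self.n_reps_community < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.atom_fraction_straw is not None:
            object.__setattr__(
                self, "delta_straw_permil",
                atom_fraction_to_delta(self.atom_fraction_straw),
            )
        if np.isclose(self.delta_straw_permil, self.delta_soil_permil):
            raise ValueError("straw label delta must differ from soil baseline delta")

    @property
    def cells(self) -> list[tuple[str, int]]:
        return [(t, d) for t in self.treatments for d in self.timepoints_days]

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        d = dict(d)
        for key in ("treatments", "timepoints_days"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CommunityTruth:
    """Planted structure of the synthetic ASV tables.

    ``effect_sizes`` maps phylum → treatment → additive log-abundance effect;
    planted co-occurrence modules mix bacterial and fungal members that share
    a latent factor with the given loading.
    """

    n_asvs_bacterial: int = 150
    n_asvs_fungal: int = 80
    library_size_bacterial: int = 20000
    library_size_fungal: int = 10000
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Ascomycota": {"CM": 1.5, "MM": 0.7},
            "Basidiomycota": {"CM": -0.8},
        }
    )
    n_modules: int = 3
    module_size_bacterial: int = 7
    module_size_fungal: int = 3
    latent_loading: float = 0.8
    baseline_log_sd: float = 1.2
    idiosyncratic_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.library_size_bacterial < 1 or self.library_size_fungal < 1:
            raise ValueError("library sizes must be >= 1")
        if not 0 <= self.latent_loading:
            raise ValueError("latent_loading must be >= 0")
        need_b = self.n_modules * self.module_size_bacterial
        need_f = self.n_modules * self.module_size_fungal
        if need_b > self.n_asvs_bacterial or need_f > self.n_asvs_fungal:
            raise ValueError("planted modules need more ASVs than available")

    @property
    def planted_modules(self) -> dict[str, int]:
        """ASV id → planted module id (1-based)."""
        modules: dict[str, int] = {}
        for m in range(self.n_modules):
            for k in range(self.module_size_bacterial):
                modules[f"bASV_{m * self.module_size_bacterial + k + 1:04d}"] = m + 1
            for k in range(self.module_size_fungal):
                modules[f"fASV_{m * self.module_size_fungal + k + 1:04d}"] = m + 1
        return modules


@dataclass
class GeneTruth:
    """Configured expectations of the qPCR gene-copy tables (copies g⁻¹ soil).

    Treatment multipliers act on the fungal markers (ITS, cbhI) so that the
    fungal:bacterial and cbhI:GH48 ratios rise with cellulose-rich
    amendments; time factors (day-28 over day-7) encode growth of both
    cellulolytic genes with bacterial markers growing faster, so both ratios
    decline over time.
    """

    copies_16s: float = 1.8e10
    copies_its: float = 1.2e9
    copies_gh48: float = 3.0e8
    copies_cbhi: float = 6.0e7
    fungal_treatment_multiplier: dict[str, float] = field(
        default_factory=lambda: {"Ctrl": 1.0, "LM": 1.3, "MM": 1.8, "CM": 3.0}
    )
    time_factor_16s: float = 1.5
    time_factor_its: float = 0.7
    time_factor_gh48: float = 3.0
    time_factor_cbhi: float = 2.0
    noise_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("copies_16s", "copies_its", "copies_gh48", "copies_cbhi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(m <= 0 for m in self.fungal_treatment_multiplier.values()):
            raise ValueError("treatment multipliers must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class GroundTruth:
    """True straw-derived and native C amounts per treatment × timepoint.

    The defining invariant is ``true_cue = mbc13/(mbc13 + co2_13)`` by
    construction; the mixing fractions follow as straw-derived over total
    pool.  Keys of the four amount dicts are ``(treatment, timepoint_days)``.
    Amounts are mg C kg⁻¹ soil.
    """

    co2_13: dict[tuple[str, int], float]
    mbc13: dict[tuple[str, int], float]
    co2_native: dict[tuple[str, int], float]
    mbc_native: dict[tuple[str, int], float]
    c_nfum_mean: float = 80.0
    kec: float = 0.45
    noise_sd_delta: float = 1.0  # ‰, Gaussian on δ values
    noise_cv_pools: float = 0.05  # log-normal CV on pool sizes
    community: CommunityTruth = field(default_factory=CommunityTruth)
    genes: GeneTruth = field(default_factory=GeneTruth)

    def __post_init__(self) -> None:
        if self.noise_sd_delta < 0 or self.noise_cv_pools < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 < self.kec <= 1:
            raise ValueError("kec must be in (0, 1]")
        for name in ("co2_13", "mbc13", "co2_native", "mbc_native"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} amounts must be >= 0")

    def true_f_co2(self, treatment: str, day: int) -> float:
        key = (treatment, day)
        return self.co2_13[key] / (self.co2_13[key] + self.co2_native[key])

    def true_f_mbc(self, treatment: str, day: int) -> float:
        key = (treatment, day)
        return self.mbc13[key] / (self.mbc13[key] + self.mbc_native[key])

    def true_cue(self, treatment: str, day: int) -> float:
        key = (treatment, day)
        return self.mbc13[key] / (self.mbc13[key] + self.co2_13[key])

    def with_noise(self, noise_sd_delta: float, noise_cv_pools: float) -> "GroundTruth":
        return replace(
            self, noise_sd_delta=noise_sd_delta, noise_cv_pools=noise_cv_pools
        )


# per-treatment presets behind default_truth(): fraction of added straw-C
# decomposed by each day, true CUE of that decomposed C, and native pool
# sizes (mg C kg^-1).  Unknown treatment labels fall back to the Ctrl row.
_DECOMPOSED = {
    "Ctrl": {7: 0.30, 28: 0.50},
    "LM": {7: 0.32, 28: 0.55},
    "MM": {7: 0.35, 28: 0.58},
    "CM": {7: 0.40, 28: 0.62},
}
_TRUE_CUE = {
    "Ctrl": {7: 0.30, 28: 0.30},
    "LM": {7: 0.35, 28: 0.32},
    "MM": {7: 0.42, 28: 0.33},
    "CM": {7: 0.55, 28: 0.35},
}
_CO2_NATIVE = {"Ctrl": {7: 120.0, 28: 240.0}}  # amended soils below
_MBC_NATIVE = {"Ctrl": 200.0}


def _preset(table: dict, treatment: str, day: int, default_scale: float = 1.0):
    row = table.get(treatment, table["Ctrl"])
    if isinstance(row, dict):
        days = sorted(row)
        # nearest configured day for non-default timepoints
        nearest = min(days, key=lambda d: abs(d - day))
        return row[nearest] * default_scale
    return row * default_scale


def default_truth(
    design: ExperimentDesign,
    noise_sd_delta: float = 1.0,
    noise_cv_pools: float = 0.05,
    community: CommunityTruth | None = None,
    genes: GeneTruth | None = None,
) -> GroundTruth:
    """Ground truth encoding the qualitative study outcome.

    Cellulose-dominant amendment (CM) decomposes straw fastest and retains
    the most straw-C in biomass at day 7 (highest CUE); by day 28 the CUE
    values converge.  Amended soils carry larger native respiration and
    biomass pools than the control.
    """
    straw_c = design.straw_c_rate * 1000.0  # mg C kg^-1 soil
    co2_13, mbc13, co2_native, mbc_native = {}, {}, {}, {}
    for trt, day in design.cells:
        dec = _preset(_DECOMPOSED, trt, day)
        cue = _preset(_TRUE_CUE, trt, day)
        key = (trt, day)
        mbc13[key] = cue * dec * straw_c
        co2_13[key] = (1.0 - cue) * dec * straw_c
        amended = trt != "Ctrl"
        co2_native[key] = _preset(_CO2_NATIVE, "Ctrl", day) * (2.0 if amended else 1.0)
        mbc_native[key] = _MBC_NATIVE["Ctrl"] * (1.5 if amended else 1.0)
    return GroundTruth(
        co2_13=co2_13,
        mbc13=mbc13,
        co2_native=co2_native,
        mbc_native=mbc_native,
        noise_sd_delta=noise_sd_delta,
        noise_cv_pools=noise_cv_pools,
        community=community or CommunityTruth(),
        genes=genes or GeneTruth(),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def generate_isotope_samples(
    design: ExperimentDesign, truth: GroundTruth
) -> pd.DataFrame:
    """Per-replicate isotope/pool measurement table for both labeling arms.

    Labeled-arm δ values sit on the mixing line at the cell's true fractions
    (plus Gaussian ‰ noise); unlabeled-arm δ values sit at the soil baseline.
    The fumigated extract is constructed by inverting the fumigation mass
    balance from the intended biomass δ, and pool sizes carry mean-preserving
    log-normal noise, so the analysis chain recovers the truth exactly when
    both noise parameters are zero.
    """
    rng = _rng(design.seed, "isotope")
    d_soil, d_straw = design.delta_soil_permil, design.delta_straw_permil
    sd = truth.noise_sd_delta
    cv = truth.noise_cv_pools
    rows = []
    for trt, day in design.cells:
        key = (trt, day)
        f_co2 = truth.true_f_co2(trt, day)
        f_mbc = truth.true_f_mbc(trt, day)
        co2_total = truth.co2_13[key] + truth.co2_native[key]
        mbc_total = truth.mbc13[key] + truth.mbc_native[key]
        for arm in ("labeled", "unlabeled"):
            for rep in range(1, design.n_reps_isotope + 1):
                if arm == "labeled":
                    cum_co2 = co2_total * _lognormal_factor(rng, cv, None)
                    mbc = mbc_total * _lognormal_factor(rng, cv, None)
                    d_co2 = d_soil + f_co2 * (d_straw - d_soil) + rng.normal(0, sd)
                    d_mbc = d_soil + f_mbc * (d_straw - d_soil) + rng.normal(0, sd)
                else:
                    cum_co2 = truth.co2_native[key] * _lognormal_factor(rng, cv, None)
                    mbc = truth.mbc_native[key] * _lognormal_factor(rng, cv, None)
                    d_co2 = d_soil + rng.normal(0, sd)
                    d_mbc = d_soil + rng.normal(0, sd)
                c_nfum = truth.c_nfum_mean * _lognormal_factor(rng, cv, None)
                c_fum = c_nfum + truth.kec * mbc
                d_nfum = d_soil + rng.normal(0, sd)
                # invert the fumigation mass balance for the fumigated extract δ
                d_fum = (d_mbc * (c_fum - c_nfum) + d_nfum * c_nfum) / c_fum
                rows.append(
                    {
                        "sample_id": f"{trt}_d{day}_{arm[0]}{rep}",
                        "treatment": trt,
                        "timepoint_days": day,
                        "arm": arm,
                        "replicate": rep,
                        "delta_co2": d_co2,
                        "cum_co2_c": cum_co2,
                        "c_fum": c_fum,
                        "c_nfum": c_nfum,
                        "delta_fum": d_fum,
                        "delta_nfum": d_nfum,
                        "delta_straw": d_straw,
                    }
                )
    return pd.DataFrame(rows)


_BACTERIAL_PHYLA = (
    ("Proteobacteria", 0.30),
    ("Actinobacteriota", 0.20),
    ("Acidobacteriota", 0.15),
    ("Chloroflexi", 0.12),
    ("Firmicutes", 0.08),
    ("Bacteroidota", 0.08),
    ("Gemmatimonadota", 0.04),
    ("Myxococcota", 0.03),
)
_FUNGAL_PHYLA = (
    ("Ascomycota", 0.55),
    ("Basidiomycota", 0.25),
    ("Mortierellomycota", 0.12),
    ("Chytridiomycota", 0.08),
)


def _community_samples(design: ExperimentDesign) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{trt}_d{day}_r{rep}",
            "treatment": trt,
            "timepoint_days": day,
            "replicate": rep,
        }
        for trt, day in design.cells
        for rep in range(1, design.n_reps_community + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _generate_domain_table(
    design: ExperimentDesign,
    truth: GroundTruth,
    domain: str,
    meta: pd.DataFrame,
    latent: np.ndarray,
) -> AsvTable:
    ct = truth.community
    rng = _rng(design.seed, "bacterial" if domain == "bacterial" else "fungal")
    n_asvs = ct.n_asvs_bacterial if domain == "bacterial" else ct.n_asvs_fungal
    library = (
        ct.library_size_bacterial if domain == "bacterial" else ct.library_size_fungal
    )
    prefix = "b" if domain == "bacterial" else "f"
    phyla_spec = _BACTERIAL_PHYLA if domain == "bacterial" else _FUNGAL_PHYLA
    asv_ids = [f"{prefix}ASV_{i + 1:04d}" for i in range(n_asvs)]
    names = [p for p, _ in phyla_spec]
    probs = np.array([w for _, w in phyla_spec])
    phyla = rng.choice(names, size=n_asvs, p=probs / probs.sum())

    for phylum in ct.effect_sizes:
        if phylum not in set(_BACTERIAL_PHYLA_NAMES) | set(_FUNGAL_PHYLA_NAMES):
            raise ValueError(f"effect size for unknown clade: {phylum!r}")

    planted = truth.community.planted_modules
    module_of = np.array([planted.get(a, 0) for a in asv_ids])
    baseline = rng.normal(0.0, ct.baseline_log_sd, size=n_asvs)
    baseline[module_of > 0] = rng.normal(0.5, 0.3, size=int((module_of > 0).sum()))

    effects = np.zeros((len(design.treatments), n_asvs))
    for ti, trt in enumerate(design.treatments):
        for ai, phylum in enumerate(phyla):
            effects[ti, ai] = ct.effect_sizes.get(phylum, {}).get(trt, 0.0)

    trt_index = {t: i for i, t in enumerate(design.treatments)}
    counts = np.zeros((len(meta), n_asvs), dtype=np.int64)
    for si, (sample, row) in enumerate(meta.iterrows()):
        log_abund = (
            baseline
            + effects[trt_index[row["treatment"]]]
            + rng.normal(0.0, ct.idiosyncratic_sd, size=n_asvs)
        )
        member = module_of > 0
        log_abund[member] = log_abund[member] + ct.latent_loading * latent[
            si, module_of[member] - 1
        ]
        p = np.exp(log_abund - log_abund.max())
        counts[si] = rng.multinomial(library, p / p.sum())

    counts_df = pd.DataFrame(counts, index=meta.index, columns=asv_ids)
    tax = pd.DataFrame({"phylum": phyla}, index=pd.Index(asv_ids, name="asv_id"))
    return AsvTable(counts_df, tax, domain, meta.copy())


_BACTERIAL_PHYLA_NAMES = tuple(p for p, _ in _BACTERIAL_PHYLA)
_FUNGAL_PHYLA_NAMES = tuple(p for p, _ in _FUNGAL_PHYLA)


def generate_asv_tables(
    design: ExperimentDesign, truth: GroundTruth
) -> tuple[AsvTable, AsvTable]:
    """Paired bacterial (16S-like) and fungal (ITS-like) ASV count tables.

    Both tables share sample metadata; planted co-occurrence modules span the
    two domains via latent factors drawn once per sample, and per-phylum
    treatment effects shift designated clades (by default an Ascomycota
    enrichment under the cellulose-dominant amendment).
    """
    if len(design.treatments) < 2:
        raise ValueError("need >=2 treatments for a community comparison")
    meta = _community_samples(design)
    # one latent draw per sample × module, shared by both domains so modules
    # are genuinely cross-domain
    latent = np.random.default_rng(
        np.random.SeedSequence([design.seed, 99])
    ).normal(size=(len(meta), truth.community.n_modules))
    bact = _generate_domain_table(design, truth, "bacterial", meta, latent)
    fungi = _generate_domain_table(design, truth, "fungal", meta, latent)
    return bact, fungi


def generate_gene_abundances(
    design: ExperimentDesign, truth: GroundTruth
) -> pd.DataFrame:
    """qPCR gene-copy table (16S, ITS, cbhI, GH48 copies g⁻¹ soil).

    Expectations follow the configured treatment multipliers and time
    factors; noise is mean-preserving log-normal, so configured orderings
    hold exactly at zero noise and in expectation otherwise.
    """
    gt = truth.genes
    rng = _rng(design.seed, "genes")
    day0 = min(design.timepoints_days)
    rows = []
    for trt, day in design.cells:
        mult = gt.fungal_treatment_multiplier.get(trt, 1.0)
        # geometric interpolation of the day-28/day-7 factor for other days
        span = 28 / 7
        expo = np.log(max(day, day0) / day0) / np.log(span) if day > day0 else 0.0
        means = {
            "copies_16s": gt.copies_16s * gt.time_factor_16s**expo,
            "copies_its": gt.copies_its * mult * gt.time_factor_its**expo,
            "copies_gh48": gt.copies_gh48 * gt.time_factor_gh48**expo,
            "copies_cbhi": gt.copies_cbhi * mult * gt.time_factor_cbhi**expo,
        }
        for rep in range(1, design.n_reps_community + 1):
            row = {
                "sample_id": f"{trt}_d{day}_r{rep}",
                "treatment": trt,
                "timepoint_days": day,
                "replicate": rep,
            }
            for gene, mean in means.items():
                row[gene] = mean * _lognormal_factor(rng, gt.noise_cv, None)
            rows.append(row)
    return pd.DataFrame(rows)


# class and group presets per amendment: the cellulose-dominant amendment is
# heterocyclic-rich, the lignin-dominant one aromatic-rich, the mixed one
# balanced between the two.
_CLASS_PRESETS = {
    "CM": {"Hete_C": 0.45, "Arom_C": 0.20, "Alip_C": 0.25, "Alic_C": 0.10},
    "LM": {"Hete_C": 0.15, "Arom_C": 0.50, "Alip_C": 0.25, "Alic_C": 0.10},
    "MM": {"Hete_C": 0.30, "Arom_C": 0.30, "Alip_C": 0.28, "Alic_C": 0.12},
}
_GROUP_PRESETS = {
    "CM": {
        "carbohydrate": 0.40, "N-containing": 0.13, "lignin": 0.06, "phenol": 0.05,
        "aromatic hydrocarbon": 0.09, "poly-aromatic hydrocarbon": 0.02,
        "saturated hydrocarbon": 0.15, "unsaturated hydrocarbon": 0.10,
    },
    "LM": {
        "lignin": 0.30, "phenol": 0.12, "aromatic hydrocarbon": 0.12,
        "poly-aromatic hydrocarbon": 0.04, "carbohydrate": 0.15,
        "N-containing": 0.05, "saturated hydrocarbon": 0.12,
        "unsaturated hydrocarbon": 0.10,
    },
    "MM": {
        "lignin": 0.18, "phenol": 0.08, "carbohydrate": 0.25, "N-containing": 0.09,
        "aromatic hydrocarbon": 0.10, "poly-aromatic hydrocarbon": 0.02,
        "saturated hydrocarbon": 0.16, "unsaturated hydrocarbon": 0.12,
    },
}


def generate_oa_composition(
    design: ExperimentDesign,
    presets: Mapping[str, Mapping[str, float]] | None = None,
) -> list[OaComposition]:
    """Pyrolysate composition of each amendment (control excluded).

    Default presets make the cellulose-dominant amendment Hete_C-dominant and
    the lignin-dominant one Arom_C-dominant, with the mixed amendment equal
    in the two classes.  User-supplied class presets are validated to sum
    to 1.
    """
    out = []
    for trt in design.treatments:
        if trt == "Ctrl":
            continue
        if presets is not None and trt in presets:
            classes = dict(presets[trt])
            groups = _GROUP_PRESETS.get(trt, _GROUP_PRESETS["MM"])
        else:
            classes = _CLASS_PRESETS.get(trt, _CLASS_PRESETS["MM"])
            groups = _GROUP_PRESETS.get(trt, _GROUP_PRESETS["MM"])
        out.append(OaComposition(trt, dict(groups), dict(classes)))
    return out


def write_fixture_dataset(directory, seed: int = 0) -> dict[str, str]:
    """Emit a small canned synthetic dataset (CSV/TSV) for tests and demos."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design = ExperimentDesign(seed=seed)
    truth = default_truth(design)
    paths: dict[str, str] = {}

    iso = generate_isotope_samples(design, truth)
    paths["isotope_samples"] = str(directory / "isotope_samples.csv")
    iso.to_csv(paths["isotope_samples"], index=False)

    bact, fungi = generate_asv_tables(design, truth)
    for name, table in (("bacterial", bact), ("fungal", fungi)):
        cp = directory / f"{name}_counts.tsv"
        tp = directory / f"{name}_taxonomy.tsv"
        mp = directory / "sample_metadata.tsv"
        table.to_tsv(cp, tp, mp)
        paths[f"{name}_counts"] = str(cp)
        paths[f"{name}_taxonomy"] = str(tp)
        paths["sample_metadata"] = str(mp)

    genes = generate_gene_abundances(design, truth)
    paths["gene_abundances"] = str(directory / "gene_abundances.csv")
    genes.to_csv(paths["gene_abundances"], index=False)

    comp = pd.DataFrame([c.to_series() for c in generate_oa_composition(design)])
    comp.index.name = "oa_label"
    paths["oa_composition"] = str(directory / "oa_composition.csv")
    comp.to_csv(paths["oa_composition"])
    return paths
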