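"""Synthetic occupational cohorts with planted auditory/microRNA structure.

The generator emulates a small cohort of industrial painters (roller and
spray, the latter more heavily exposed to both noise and solvent vapours)
plus non-exposed controls.  A latent per-subject "damage" variable is driven
by daily noise level, cumulative solvent metabolite dose and DNA-repair
genotype (hOGG1); it raises audiometric hearing level (HL), lowers
distortion-product otoacoustic emission (DPOAE) band levels with a low/mid
frequency emphasis, and shifts the abundance of coupled microRNAs in the
sequencing counts.  Every random draw descends from a single integer seed,
so a configuration reproduces bit-identical cohorts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .expression import CountMatrix

__all__ = [
    "HL_FREQUENCIES",
    "DPOAE_BAND_CENTERS",
    "COUPLED_MIRNA_DEFAULTS",
    "CohortConfig",
    "PlantedEffects",
    "Subject",
    "generate_subjects",
    "generate_audiology",
    "generate_counts",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Standard octave + inter-octave audiometric grid, 125-8000 Hz (11 points).
HL_FREQUENCIES: tuple[int, ...] = (
    125, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000,
)

#: Third-octave DPOAE band centers, labelled by f_DP (Hz).
DPOAE_BAND_CENTERS: tuple[int, ...] = (1153, 1452, 1830, 2305, 2904)

#: Default planted differential-expression effects: analogues of the twelve
#: microRNAs found both differentially expressed and correlated with an
#: audiological variable.  Columns: (name, log2 fold change exposed vs
#: control, coupled outcome, correlation sign with that outcome).
COUPLED_MIRNA_DEFAULTS: tuple[tuple[str, float, str, int], ...] = (
    ("hsa-miR-885-3p", -3.72, "HL", -1),
    ("hsa-miR-122-5p", -3.14, "HL", -1),
    ("hsa-miR-195-5p", -1.82, "HL", -1),
    ("hsa-miR-375", -2.72, "HL", -1),
    ("hsa-miR-483-5p", -2.20, "HL", -1),
    ("hsa-miR-193b-5p", -1.81, "HL", -1),
    ("hsa-miR-497-5p", -2.64, "DPOAE", -1),
    ("hsa-miR-206", -3.01, "DPOAE", -1),
    ("hsa-miR-486-5p", -1.39, "DPOAE", +1),
    ("hsa-miR-2355-5p", 7.77, "DPOAE", -1),
    ("hsa-miR-873-3p", 7.74, "DPOAE", -1),
    ("hsa-miR-92b-5p", -1.41, "DPOAE", +1),
)

_METABOLITE_MEDIANS = {
    "MA": 7523.0,
    "PGA": 4441.9,
    "MHIPP": 68974.0,
    "SPMA": 1.78,
    "SBMA": 14.59,
    "cotinine": 1180.8,
}

_GENOTYPES = ("wt", "het", "mut")


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reflect the reference occupational setting: 11 roller painters
    and 6 spray painters aged 21-54, daily A-weighted noise exposure
    averaging 81.7 / 87.2 dB(A) for the two trades, urinary solvent
    metabolite medians in ug/g creatinine, plus an equally sized
    non-exposed control group.
    """

    n_roller: int = 11
    n_spray: int = 6
    n_controls: int = 17
    age_range: tuple[float, float] = (21.0, 54.0)
    noise_mean_roller: float = 81.7
    noise_mean_spray: float = 87.2
    noise_sd: float = 2.5
    noise_baseline: float = 70.0  # dB(A) attributed to non-exposed controls
    metabolite_medians: dict[str, float] = field(
        default_factory=lambda: dict(_METABOLITE_MEDIANS)
    )
    metabolite_log_sd: float = 0.6  # log-normal spread of metabolite levels
    spray_dose_ratio: float = 2.0  # spray painters' median uplift
    exposure_years_range: tuple[float, float] = (2.0, 25.0)
    allele_freq_hOGG1: float = 0.3
    allele_freq_XRCC1: float = 0.3
    # latent damage: noise slope (dB HL per dB(A) above baseline), dose
    # slope (dB HL per SD of log cumulative dose above the cohort minimum),
    # genotype multiplier for the mut variant (het gets the midpoint, wt
    # gets 1; the multiplied dose score is non-negative, so mut >= wt).
    damage_coefficients: tuple[float, float, float] = (0.6, 3.5, 1.6)
    damage_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_roller", "n_spray", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("allele_freq_hOGG1", "allele_freq_XRCC1"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(v <= 0 for v in self.metabolite_medians.values()):
            raise ValueError("metabolite medians must be positive")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["exposure_years_range"] = list(self.exposure_years_range)
        d["damage_coefficients"] = list(self.damage_coefficients)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        d = yaml.safe_load(text)
        for key in ("age_range", "exposure_years_range", "damage_coefficients"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlantedEffects:
    """Ground-truth effects planted into counts and audiology.

    ``de_mirnas`` lists (gene, log2fc) exposed-vs-control shifts;
    ``coupling`` maps gene -> (outcome, sign, slope) where slope is the
    log2-abundance shift per SD of latent damage and sign is the intended
    correlation sign with the outcome (HL rises with damage, DPOAE falls).
    ``hl_profile`` / ``dp_profile`` weight the damage contribution per
    frequency/band, with low/mid frequencies emphasized.
    """

    de_mirnas: list[tuple[str, float]]
    coupling: dict[str, tuple[str, int, float]]
    dispersion: float = 0.1
    hl_profile: dict[int, float] = field(default_factory=dict)
    dp_profile: dict[int, float] = field(default_factory=dict)
    hl_noise_sd: float = 4.0  # per-ear measurement + subject scatter, dB
    dp_noise_sd: float = 4.0
    hl_age_slope: dict[int, float] = field(default_factory=dict)  # dB/decade
    hl_baseline: float = 12.0  # dB HL at the young-adult reference age
    dp_baseline: float = 30.0  # dB EPL of an undamaged cochlea

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not self.hl_profile:
            self.hl_profile = {
                125: 1.0, 250: 1.0, 500: 1.0, 750: 1.0, 1000: 1.0,
                1500: 1.0, 2000: 1.0, 3000: 0.8, 4000: 0.7, 6000: 0.5, 8000: 0.5,
            }
        if not self.dp_profile:
            self.dp_profile = {1153: 1.0, 1452: 1.0, 1830: 0.9, 2305: 0.8, 2904: 0.7}
        if not self.hl_age_slope:
            self.hl_age_slope = {
                125: 1.0, 250: 1.0, 500: 1.0, 750: 1.2, 1000: 1.2,
                1500: 1.5, 2000: 2.0, 3000: 2.5, 4000: 3.0, 6000: 3.5, 8000: 4.0,
            }
        low = max(self.hl_profile[f] for f in self.hl_profile if f <= 2000)
        high = max(self.hl_profile[f] for f in self.hl_profile if f >= 6000)
        if high > low:
            raise ValueError("hl_profile must not weight >=6 kHz above <=2 kHz")

    @classmethod
    def default(cls, n_extra_de: int = 0, **kwargs) -> "PlantedEffects":
        """Twelve named audiology-coupled effects, plus optional extra
        (uncoupled) differentially expressed genes to reach a larger DE set.
        """
        de = [(name, lfc) for name, lfc, _, _ in COUPLED_MIRNA_DEFAULTS]
        coupling = {
            name: (outcome, sign, 1.0)
            for name, _, outcome, sign in COUPLED_MIRNA_DEFAULTS
        }
        rng = np.random.default_rng(12345)  # fixed: these are design constants
        for k in range(n_extra_de):
            lfc = float(rng.choice([-1, 1]) * rng.uniform(1.5, 3.5))
            de.append((f"hsa-miR-extra-{k:03d}", lfc))
        return cls(de_mirnas=de, coupling=coupling, **kwargs)


@dataclass
class Subject:
    id: str
    group: str  # roller | spray | control
    age: float
    L_ex8h: float
    metabolites: dict[str, float]
    exposure_years: float
    dose: dict[str, float]
    hOGG1: str
    XRCC1: str
    damage: float  # latent ground truth, hidden from the analysis stages


def _draw_genotype(rng: np.random.Generator, q: float, n: int) -> np.ndarray:
    """Hardy-Weinberg genotype draw at minor-allele frequency q."""
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    return rng.choice(np.array(_GENOTYPES), size=n, p=probs / probs.sum())


def generate_subjects(config: CohortConfig) -> list[Subject]:
    """Draw a cohort of exposed painters and non-exposed controls.

    Noise is Normal around the trade mean; metabolites are log-normal around
    trade-scaled medians (spray > roller); genotypes follow Hardy-Weinberg;
    the latent damage combines noise above baseline, standardized log
    cumulative dose scaled by the hOGG1 genotype multiplier, and Gaussian
    subject scatter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    groups = (
        ["roller"] * config.n_roller
        + ["spray"] * config.n_spray
        + ["control"] * config.n_controls
    )
    n = len(groups)
    ages = rng.uniform(*config.age_range, size=n)
    geno_ogg1 = _draw_genotype(rng, config.allele_freq_hOGG1, n)
    geno_xrcc1 = _draw_genotype(rng, config.allele_freq_XRCC1, n)
    c_noise, c_dose, g_mut = config.damage_coefficients
    g_mult = {"wt": 1.0, "het": (1.0 + g_mut) / 2.0, "mut": g_mut}

    subjects: list[Subject] = []
    raw: list[dict] = []
    for i, group in enumerate(groups):
        if group == "control":
            noise = config.noise_baseline
            mets = {m: 0.0 for m in config.metabolite_medians}
            mets["cotinine"] = float(
                config.metabolite_medians.get("cotinine", 0.0)
                * rng.lognormal(0.0, config.metabolite_log_sd)
            )
            years = 0.0
        else:
            mean = (
                config.noise_mean_spray if group == "spray" else config.noise_mean_roller
            )
            noise = float(rng.normal(mean, config.noise_sd))
            scale = config.spray_dose_ratio if group == "spray" else 1.0
            mets = {
                m: float(med * scale * rng.lognormal(0.0, config.metabolite_log_sd))
                for m, med in config.metabolite_medians.items()
            }
            if "cotinine" in mets:  # smoking is not an occupational exposure
                mets["cotinine"] = float(
                    config.metabolite_medians["cotinine"]
                    * rng.lognormal(0.0, config.metabolite_log_sd)
                )
            years = float(rng.uniform(*config.exposure_years_range))
        dose = {
            m: (v * years if m != "cotinine" else 0.0) for m, v in mets.items()
        }
        raw.append(
            dict(group=group, age=float(ages[i]), noise=noise, mets=mets,
                 years=years, dose=dose, ogg1=str(geno_ogg1[i]), xrcc1=str(geno_xrcc1[i]))
        )

    # log cumulative solvent dose, scaled by the cohort SD and shifted to
    # start at zero: a non-negative harm score, so the genotype multiplier
    # shifts damage upward (mut >= het >= wt) instead of widening it
    total_dose = np.array([sum(r["dose"].values()) for r in raw])
    logd = np.log1p(total_dose)
    sd = logd.std()
    z = (logd - logd.min()) / sd if sd > 0 else np.zeros_like(logd)

    scatter = rng.normal(0.0, config.damage_sd, size=n)
    for i, r in enumerate(raw):
        damage = (
            c_noise * (r["noise"] - config.noise_baseline)
            + c_dose * z[i] * g_mult[r["ogg1"]]
            + scatter[i]
        )
        subjects.append(
            Subject(
                id=f"S{i + 1:03d}",
                group=r["group"],
                age=r["age"],
                L_ex8h=r["noise"],
                metabolites=r["mets"],
                exposure_years=r["years"],
                dose=r["dose"],
                hOGG1=r["ogg1"],
                XRCC1=r["xrcc1"],
                damage=float(damage),
            )
        )
    return subjects


def _damage_z(subjects: list[Subject]) -> np.ndarray:
    d = np.array([s.damage for s in subjects])
    sd = d.std()
    return (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)


def _damage_z_within_condition(subjects: list[Subject]) -> np.ndarray:
    """Damage standardized by the cohort SD but centered within exposure
    condition, so count coupling adds no exposed-vs-control mean shift on
    top of the planted fold changes."""
    d = np.array([s.damage for s in subjects])
    exposed = np.array([s.group != "control" for s in subjects])
    sd = d.std()
    if sd == 0:
        return np.zeros_like(d)
    out = d.copy()
    for mask in (exposed, ~exposed):
        if mask.any():
            out[mask] -= d[mask].mean()
    return out / sd


def generate_audiology(
    subjects: list[Subject],
    effects: PlantedEffects,
    seed: int = 0,
    ear_average: bool = True,
    quantize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject HL (dB HL) and DPOAE (dB EPL) tables from latent damage.

    Each quantity is generated per ear, the HL quantized to the audiometer's
    5 dB steps, then the two ears averaged (the per-subject value used by
    all analyses).  HL rises and DPOAE falls with damage, through the
    frequency-profiles of the planted effects.
    """
    if not subjects:
        raise ValueError("empty subject list")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_ears = 2 if ear_average else 1
    ids = [s.id for s in subjects]

    hl = np.zeros((len(subjects), len(HL_FREQUENCIES)))
    for i, s in enumerate(subjects):
        ears = np.zeros((n_ears, len(HL_FREQUENCIES)))
        for e in range(n_ears):
            for k, f in enumerate(HL_FREQUENCIES):
                base = effects.hl_baseline + effects.hl_age_slope[f] * (s.age - 20.0) / 10.0
                level = base + effects.hl_profile[f] * s.damage
                level += rng.normal(0.0, effects.hl_noise_sd)
                ears[e, k] = 5.0 * np.round(level / 5.0) if quantize else level
        hl[i] = ears.mean(axis=0)

    dp = np.zeros((len(subjects), len(DPOAE_BAND_CENTERS)))
    for i, s in enumerate(subjects):
        ears = np.zeros((n_ears, len(DPOAE_BAND_CENTERS)))
        for e in range(n_ears):
            for k, c in enumerate(DPOAE_BAND_CENTERS):
                level = effects.dp_baseline - effects.dp_profile[c] * s.damage
                level += rng.normal(0.0, effects.dp_noise_sd)
                ears[e, k] = level
        dp[i] = ears.mean(axis=0)

    hl_df = pd.DataFrame(hl, index=ids, columns=[f"F{f}" for f in HL_FREQUENCIES])
    dp_df = pd.DataFrame(dp, index=ids, columns=[f"DP{c}" for c in DPOAE_BAND_CENTERS])
    hl_df.index.name = dp_df.index.name = "subject"
    return hl_df, dp_df


def generate_counts(
    subjects: list[Subject],
    effects: PlantedEffects,
    n_genes: int = 200,
    mean_depth: float = 1e6,
    seed: int = 0,
    libsize_log_sd: float = 0.3,
) -> CountMatrix:
    """Negative-binomial microRNA counts with planted fold changes.

    Baseline relative abundances are log-normal across genes; library sizes
    are log-normal around ``mean_depth``.  Genes in ``effects.de_mirnas``
    get their log2 fold change in exposed subjects; genes in
    ``effects.coupling`` additionally shift log2-linearly with each
    subject's standardized latent damage, with the sign that induces the
    planted correlation (positive damage raises HL and lowers DPOAE).
    """
    if not subjects:
        raise ValueError("empty subject list")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if effects.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))

    planted = [name for name, _ in effects.de_mirnas]
    for name in effects.coupling:
        if name not in planted:
            planted.append(name)
    if n_genes < len(planted):
        raise ValueError(f"n_genes must be at least {len(planted)}")
    genes = planted + [f"hsa-miR-null-{k:04d}" for k in range(n_genes - len(planted))]

    base_log = rng.normal(0.0, 1.5, size=n_genes)
    lfc = dict(effects.de_mirnas)
    exposed = np.array([s.group != "control" for s in subjects], dtype=float)
    dz = _damage_z_within_condition(subjects)
    libsize = mean_depth * rng.lognormal(0.0, libsize_log_sd, size=len(subjects))

    log2_mu = np.tile(base_log[:, None] / np.log(2.0), (1, len(subjects)))
    for g, gene in enumerate(genes):
        if gene in lfc:
            # strongly upregulated genes start near the detection limit and
            # rise into the normal abundance range, as in real libraries;
            # without this the largest planted effects would dominate the
            # exposed libraries and distort every other gene's share
            log2_mu[g] -= max(lfc[gene], 0.0)
            log2_mu[g] += lfc[gene] * exposed
        if gene in effects.coupling:
            outcome, sign, slope = effects.coupling[gene]
            direction = sign if outcome == "HL" else -sign
            log2_mu[g] += direction * slope * dz

    rel = 2.0 ** log2_mu
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * libsize

    if effects.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / effects.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    ids = [s.id for s in subjects]
    condition = pd.Series(
        {s.id: ("control" if s.group == "control" else "exposed") for s in subjects}
    )
    df = pd.DataFrame(counts, index=genes, columns=ids)
    df.index.name = "gene"
    return CountMatrix(counts=df, condition=condition)


def subjects_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Flatten subjects into the tab-separated cohort-table schema."""
    rows = []
    for s in subjects:
        row = {
            "subject": s.id,
            "group": s.group,
            "age": s.age,
            "L_ex8h": s.L_ex8h,
            "exposure_years": s.exposure_years,
            "hOGG1": s.hOGG1,
            "XRCC1": s.XRCC1,
            "damage": s.damage,
        }
        for m, v in s.metabolites.items():
            row[f"met_{m}"] = v
        for m, v in s.dose.items():
            row[f"dose_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def generate_cohort(
    config: CohortConfig,
    effects: PlantedEffects | None = None,
    n_genes: int = 200,
    mean_depth: float = 1e6,
) -> dict:
    """Full synthetic dataset: subjects, audiology, counts, ground truth."""
    effects = effects if effects is not None else PlantedEffects.default()
    subjects = generate_subjects(config)
    hl, dp = generate_audiology(subjects, effects, seed=config.seed)
    cm = generate_counts(
        subjects, effects, n_genes=n_genes, mean_depth=mean_depth, seed=config.seed
    )
    return {
        "subjects": subjects,
        "cohort": subjects_frame(subjects),
        "hl": hl,
        "dpoae": dp,
        "counts": cm,
        "effects": effects,
        "config": config,
    }


_COHORT_REQUIRED = ("group", "age", "L_ex8h", "exposure_years", "hOGG1", "XRCC1")


class SchemaError(ValueError):
    pass


def write_cohort(tables: dict, directory: str | os.PathLike) -> None:
    """Write cohort/audiology/count tables as tab-separated text files."""
    cohort: pd.DataFrame = tables["cohort"]
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    os.makedirs(directory, exist_ok=True)
    fmt = dict(sep="\t", float_format="%.10g")
    cohort.to_csv(os.path.join(directory, "cohort.tsv"), **fmt)
    tables["hl"].to_csv(os.path.join(directory, "hl.tsv"), **fmt)
    tables["dpoae"].to_csv(os.path.join(directory, "dpoae.tsv"), **fmt)
    cm: CountMatrix = tables["counts"]
    cm.counts.to_csv(os.path.join(directory, "counts.tsv"), **fmt)
    cond = cm.condition.rename("condition").to_frame()
    cond.index.name = "subject"
    cond.to_csv(os.path.join(directory, "condition.tsv"), sep="\t")


def read_cohort(directory: str | os.PathLike) -> dict:
    """Read tables written by :func:`write_cohort`, validating schemas."""
    def _read(name: str) -> pd.DataFrame:
        path = os.path.join(directory, name)
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise SchemaError(f"{name} is empty")
        return df

    cohort = _read("cohort.tsv")
    missing = [c for c in _COHORT_REQUIRED if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort.tsv missing column(s): {missing}")
    hl = _read("hl.tsv")
    dp = _read("dpoae.tsv")
    counts = _read("counts.tsv")
    for name, df in (("hl.tsv", hl), ("dpoae.tsv", dp), ("counts.tsv", counts)):
        nonnum = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if nonnum:
            raise SchemaError(f"{name} has non-numeric column(s): {nonnum}")
    cond_df = _read("condition.tsv")
    if "condition" not in cond_df.columns:
        raise SchemaError("condition.tsv missing column(s): ['condition']")
    cm = CountMatrix(counts=counts, condition=cond_df["condition"])
    return {"cohort": cohort, "hl": hl, "dpoae": dp, "counts": cm}
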