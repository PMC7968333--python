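"""Synthetic herd generator with known genetic truth.

Generates the four inputs of the analysis — pedigree, SNP genotypes,
hourly weather and reproductive event records — under the linear reaction
norm model

    y_i = fixed_i + a0_i + x_i * a1_i + e_i

so that every downstream stage (gradients, kinship, REML, diagnostics,
ssGWAS) can be exercised against configured truth.  The per-animal
intercept/slope breeding values (a0, a1) follow the configured 2x2
covariance; their genomic part is an exact weighted sum of simulated SNP
effects (gene content times allele substitution effect), or drawn down
the pedigree as a polygenic process when no genotype signal is wanted.

The binary conception-rate trait is generated from a clamped linear
probability model (not a liability threshold), so the linear analysis
model is correctly specified and parameter recovery is exact in
expectation; a liability option exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import gradients
from .gradients import EGSpec
from .kinship import Pedigree, inbreeding

#: generating (co)variance components per trait on the prop-gradient
#: reference-window scale: (sigma_a0^2, sigma_a1^2, sigma_a0a1, sigma_e^2).
DEFAULT_COMPONENTS = {
    "AFC": (971.97, 0.53, -9.62, 3413.70),
    "IFL": (218.16, 0.25, -1.80, 2456.90),
    "CR": (1.01e-2, 1.60e-5, -3.35e-4, 1.99e-1),
}

DEFAULT_TRAIT_MEANS = {"AFC": 769.0, "IFL": 29.0, "CR": 0.59}


@dataclass
class SimConfig:
    """Configuration of the synthetic population and weather.

    Variance components default to the reference-window prop-gradient
    estimates for the three fertility traits (days^2 for AFC/IFL,
    dimensionless for CR).  The pedigree is bred over ``n_generations``
    (>= 3); only final-generation females are phenotyped, and each
    final-round sire has ``daughters_per_sire`` phenotyped daughters so
    the >= 20-daughter re-ranking filter is exercisable.
    """

    n_sires: int = 40
    daughters_per_sire: int = 25
    n_generations: int = 3
    n_herds: int = 15
    n_snps: int = 1000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    years: tuple[int, int] = (2012, 2014)
    variance_components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    fixed_effect_sds: dict = field(
        default_factory=lambda: {"hym": 8.0, "technician": 4.0, "semen_type": 2.0}
    )
    n_technicians: int = 20
    eg_spec: EGSpec = field(default_factory=lambda: EGSpec("prop", (-30, 30)))
    architecture: Literal["genomic", "polygenic"] = "genomic"
    cr_model: Literal["linear", "liability"] = "linear"
    intermediate_daughters: int = 4
    gestation_days: int = 280
    dams_known: bool = True
    seed: int = 20210317

    def __post_init__(self):
        if self.n_generations < 3:
            raise ValueError("n_generations must be >= 3")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        for trait, (v0, v1, c01, ve) in self.variance_components.items():
            sig = np.array([[v0, c01], [c01, v1]])
            if np.any(np.linalg.eigvalsh(sig) < -1e-12 * max(v0, v1, 1.0)):
                raise ValueError(f"intercept/slope covariance for {trait} not PSD")
            if ve <= 0:
                raise ValueError(f"residual variance for {trait} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueValues:
    """Generating truth for one simulated population."""

    a0: dict            # trait -> per-animal intercept breeding values
    a1: dict            # trait -> per-animal slope breeding values
    snp_effects: dict   # trait -> (m, 2) allele substitution effects, or None
    eg: np.ndarray      # per-phenotyped-heifer gradient value (true window)
    phenotyped_idx: np.ndarray
    fixed_effects: dict


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Breed a pedigree of >= 3 generations with a sire-daughter structure.

    Generation 0 holds founder sires and dams; each later generation
    breeds a fresh sire cohort plus females; the final generation consists
    of ``n_sires * daughters_per_sire`` heifers, sired by the previous
    cohort.  Every non-founder has both parents recorded (or, when
    ``dams_known`` is false, a recorded sire and unknown dam, the common
    field situation for large commercial pedigrees).
    """
    rng = rng or config.rng()
    ids, sire, dam, sex, gen = [], [], [], [], []

    def add(s_idx, d_idx, is_male, g):
        ids.append(len(ids) + 1)
        sire.append(s_idx)
        dam.append(d_idx)
        sex.append("M" if is_male else "F")
        gen.append(g)
        return len(ids) - 1

    n_found_dams = max(config.n_sires * 2, config.intermediate_daughters * config.n_sires)
    sires_prev = [add(-1, -1, True, 0) for _ in range(config.n_sires)]
    dams_prev = [add(-1, -1, False, 0) for _ in range(n_found_dams)]

    for g in range(1, config.n_generations):
        final = g == config.n_generations - 1
        dps = config.daughters_per_sire if final else config.intermediate_daughters
        new_sires, new_dams = [], []
        if not final:
            for _ in range(config.n_sires):
                s = sires_prev[rng.integers(len(sires_prev))]
                d = dams_prev[rng.integers(len(dams_prev))]
                new_sires.append(add(s, d, True, g))
        for s in sires_prev:
            for _ in range(dps):
                d = dams_prev[rng.integers(len(dams_prev))]
                d_rec = d if config.dams_known else -1
                new_dams.append(add(s, d_rec, False, g))
        sires_prev = new_sires or sires_prev
        dams_prev = new_dams

    meta = pd.DataFrame({"sex": sex, "generation": gen})
    return Pedigree(np.asarray(ids), np.asarray(sire), np.asarray(dam), meta=meta)


def phenotyped_indices(ped: Pedigree) -> np.ndarray:
    """Positions of the phenotyped cohort: final-generation females."""
    gen = ped.meta["generation"].to_numpy()
    sex = ped.meta["sex"].to_numpy()
    return np.where((gen == gen.max()) & (sex == "F"))[0]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    ped: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
):
    """Gene-drop genotypes through the pedigree.

    Founder haplotypes are Bernoulli draws at per-SNP frequencies uniform
    over ``maf_range``; offspring receive one allele per locus sampled
    from each known parent's pair (an unknown parent contributes a
    population draw).  Returns ``(genotypes, snp_map, freqs)`` with
    genotypes coded 0/1/2.
    """
    rng = rng or config.rng()
    n, m = ped.n, config.n_snps
    freqs = rng.uniform(*config.maf_range, size=m)
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = (np.arange(m) // per_chrom + 1).astype(int)
    bp = np.concatenate(
        [np.sort(rng.integers(1, 100_000_000, size=(chrom == c).sum()))
         for c in np.unique(chrom)]
    )
    snp_map = pd.DataFrame({"snp": [f"snp{j + 1}" for j in range(m)], "chrom": chrom, "bp": bp})

    hap = np.zeros((2, n, m), dtype=np.int8)
    for i in range(n):
        for k, p in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if p < 0:
                hap[k, i] = rng.random(m) < freqs
            else:
                pick = rng.integers(2, size=m)
                hap[k, i] = hap[pick, p, np.arange(m)]
    geno = (hap[0] + hap[1]).astype(np.int8)
    return geno, snp_map, freqs


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def simulate_weather(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hourly dry-bulb and dew-point series with seasonal and diurnal cycles.

    A continental-climate emulation: annual sinusoid (amplitude 16 deg C
    around an 11 deg C mean), diurnal sinusoid (amplitude 7 deg C peaking
    mid-afternoon), Gaussian noise, and a dew-point depression that
    shrinks in the humid summer.  Under the defaults the hourly THI spans
    roughly 15-85 over a year, so the proportion gradient attains [0, 1]
    and the minimum-THI gradient sweeps its plotted [15, 75] axis, with
    within-day THI swings of tens of units.  Coverage extends 120 days
    beyond the configured years on both sides so that critical-period
    windows anchored near year boundaries stay inside the data.
    """
    rng = rng or config.rng()
    start = pd.Timestamp(f"{config.years[0]}-01-01") - pd.Timedelta(days=120)
    end = pd.Timestamp(f"{config.years[1]}-12-31") + pd.Timedelta(days=120)
    t = pd.date_range(start, end, freq="h")
    doy = t.dayofyear.to_numpy()
    hour = t.hour.to_numpy()
    season = np.sin(2 * np.pi * (doy - 100) / 365.25)
    diurnal = np.cos(2 * np.pi * (hour - 15) / 24)
    tdb = 11.0 + 16.0 * season + 7.0 * diurnal + rng.normal(0.0, 2.5, len(t))
    depression = 12.0 - 8.0 * (1 + season) / 2 + rng.normal(0.0, 1.5, len(t))
    tdp = tdb - np.maximum(depression, 0.5)
    return pd.DataFrame({"time": t, "tdb_c": tdb, "tdp_c": tdp})


# ---------------------------------------------------------------------------
# breeding values and phenotypes
# ---------------------------------------------------------------------------

def _chol2(v0, v1, c01):
    sig = np.array([[v0, c01], [c01, v1]])
    # tolerate a semi-definite configured covariance
    w, V = np.linalg.eigh(sig)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w))


def _genomic_bvs(geno, freqs, comps, rng):
    """SNP effects scaled so founder-genomic variance matches the config."""
    m = geno.shape[1]
    scale = 2.0 * np.sum(freqs * (1 - freqs))
    L = _chol2(comps[0], comps[1], comps[2]) / np.sqrt(scale)
    eff = rng.standard_normal((m, 2)) @ L.T
    M = geno.astype(float) - 2.0 * freqs
    bv = M @ eff
    return bv[:, 0], bv[:, 1], eff


def _polygenic_bvs(ped, comps, rng):
    L = _chol2(comps[0], comps[1], comps[2])
    F = inbreeding(ped)
    n = ped.n
    a = np.zeros((n, 2))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            a[i] = L @ rng.standard_normal(2)
        else:
            par = np.zeros(2)
            w = 0.0
            fsum = 0.0
            for p in (s, d):
                if p >= 0:
                    par += 0.5 * a[p]
                    w += 0.25
                    fsum += F[p]
            # Mendelian sampling variance given the known parents
            msv = 1.0 - w - 0.25 * fsum
            a[i] = par + np.sqrt(max(msv, 0.0)) * (L @ rng.standard_normal(2))
    return a[:, 0], a[:, 1]


def simulate_phenotypes(
    ped: Pedigree,
    genotypes,
    weather: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    snp_freqs: np.ndarray | None = None,
):
    """Generate reproductive event records under the reaction norm model.

    First-service dates are uniform over the configured years so the
    gradient is well populated; the true-window gradient value x enters
    the record as ``fixed + a0 + x a1 + e`` for AFC and IFL, and through
    a clamped linear probability for CR.  Event dates are constructed to
    be mutually consistent: the last service equals first service plus
    IFL, calving follows the last service by ``gestation_days``, and the
    birth date is set so that age at first calving equals the generated
    AFC (hence AFC = age at conception + gestation).  A heifer pregnant
    at first service has IFL = 0.

    Returns ``(records, TrueValues)`` where ``records`` is a raw event
    table consumable by :func:`reactnorm.phenotypes.derive_traits`.
    """
    rng = rng or config.rng()
    pidx = phenotyped_indices(ped)
    n_ph = len(pidx)

    missing = {"AFC", "IFL", "CR"} - set(config.variance_components)
    if missing:
        raise ValueError(f"variance components missing for traits: {sorted(missing)}")

    daily = gradients.daily_summaries(weather)
    # weather extends 120 d beyond the configured years, so services inside
    # the years leave room for any candidate window in [-90, +60]
    lo = pd.Timestamp(f"{config.years[0]}-01-01")
    hi = pd.Timestamp(f"{config.years[1]}-12-31")
    span = (hi - lo).days
    service = lo + pd.to_timedelta(rng.integers(0, span + 1, size=n_ph), unit="D")
    x = gradients.eg_values(config.eg_spec, daily, service)

    herd = rng.integers(1, config.n_herds + 1, size=n_ph)
    tech = rng.integers(1, config.n_technicians + 1, size=n_ph)
    semen = np.where(rng.random(n_ph) < 0.5, "conventional", "sexed")

    a0, a1, snp_eff, fixed_draws = {}, {}, {}, {}
    values = {}
    for trait, comps in config.variance_components.items():
        if config.architecture == "genomic":
            if genotypes is None:
                raise ValueError("genomic architecture requires genotypes")
            freqs = (
                snp_freqs
                if snp_freqs is not None
                else np.asarray(genotypes, dtype=float).mean(axis=0) / 2.0
            )
            t0, t1, eff = _genomic_bvs(np.asarray(genotypes), freqs, comps, rng)
            snp_eff[trait] = eff
        else:
            t0, t1 = _polygenic_bvs(ped, comps, rng)
            snp_eff[trait] = None
        a0[trait], a1[trait] = t0, t1

        sds = config.fixed_effect_sds
        scale = 1.0 if trait != "CR" else 0.01
        hym_key = pd.Series(herd).astype(str) + "-" + pd.Series(service).dt.strftime("%Y-%m")
        hym_levels = {k: rng.normal(0, sds.get("hym", 0.0) * scale) for k in sorted(hym_key.unique())}
        tech_levels = {k: rng.normal(0, sds.get("technician", 0.0) * scale) for k in range(1, config.n_technicians + 1)}
        semen_eff = rng.normal(0, sds.get("semen_type", 0.0) * scale)
        fixed = (
            hym_key.map(hym_levels).to_numpy()
            + pd.Series(tech).map(tech_levels).to_numpy()
            + np.where(semen == "sexed", semen_eff, 0.0)
        )
        fixed_draws[trait] = {"hym": hym_levels, "technician": tech_levels, "semen_sexed": semen_eff}

        genetic = t0[pidx] + x * t1[pidx]
        mu = config.trait_means[trait]
        if trait == "CR":
            if config.cr_model == "linear":
                p = np.clip(mu + fixed + genetic, 0.0, 1.0)
                values[trait] = (rng.random(n_ph) < p).astype(int)
            else:
                liab = mu + fixed + genetic + rng.normal(0, np.sqrt(comps[3]), n_ph)
                values[trait] = (liab > 0.5).astype(int)
        else:
            e = rng.normal(0.0, np.sqrt(comps[3]), n_ph)
            values[trait] = mu + fixed + genetic + e

    cr = values["CR"]
    ifl = np.where(cr == 1, 0, np.maximum(np.round(values["IFL"]), 1)).astype(int)
    afc = np.round(values["AFC"]).astype(int)
    last_service = service + pd.to_timedelta(ifl, unit="D")
    calving = last_service + pd.Timedelta(days=config.gestation_days)
    birth = calving - pd.to_timedelta(afc, unit="D")

    records = pd.DataFrame(
        {
            "heifer_id": ped.ids[pidx],
            "herd": herd,
            "herd_calving": herd,
            "birth_date": birth,
            "first_service_date": service,
            "last_service_date": last_service,
            "calving_date": calving,
            "conceived_first": cr,
            "technician": tech,
            "semen_type": semen,
        }
    )
    truth = TrueValues(
        a0=a0, a1=a1, snp_effects=snp_eff, eg=x,
        phenotyped_idx=pidx, fixed_effects=fixed_draws,
    )
    return records, truth


def simulate_all(config: SimConfig):
    """Convenience wrapper: pedigree, genotypes, weather, records, truth."""
    rng = config.rng()
    ped = simulate_pedigree(config, rng)
    geno, snp_map, freqs = simulate_genotypes(ped, config, rng)
    weather = simulate_weather(config, rng)
    records, truth = simulate_phenotypes(
        ped, geno, weather, config, rng, snp_freqs=freqs
    )
    return ped, geno, snp_map, weather, records, truth
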