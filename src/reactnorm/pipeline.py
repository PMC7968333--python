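"""End-to-end pipeline: simulate/load -> gradients -> kinship -> RNM -> reports.

A declarative :class:`RunConfig` (JSON-friendly) drives the stages in
order, writing every intermediate artifact as plain text (CSV/JSON) with
SHA-256 checksums and a manifest sufficient to re-run bit-identically:
the manifest records the config hash, the seed and every artifact
digest, and all randomness flows through one seeded generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diagnostics, gwas, io
from .gradients import EGSpec, candidate_windows, daily_summaries, eg_values, scan_critical_period
from .kinship import Kinship, qc_genotypes
from .phenotypes import derive_traits, edit_filters
from .reml import ReactionNormModel
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)

S1_WINDOW = (-30, 30)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str
    seed: int = 1
    traits: tuple = ("AFC",)
    eg_kinds: tuple = ("prop",)
    scenarios: tuple = ("S1",)
    kinship: str = "A"
    omega: float = 0.05
    thi_threshold: float = 72.0
    min_run_hours: int = 6
    accuracy_threshold: float = 0.4
    top_fraction: float = 0.005
    min_daughters: int = 20
    simulate: dict | None = None
    paths: dict | None = None

    def sim_config(self) -> SimConfig:
        kw = dict(self.simulate or {})
        kw.setdefault("seed", self.seed)
        return SimConfig(**kw)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns the list of problems found."""
    errors = []
    if not config.traits:
        errors.append("trait list is empty")
    for t in config.traits:
        if t not in ("AFC", "IFL", "CR"):
            errors.append(f"unknown trait {t!r}")
    for k in config.eg_kinds:
        if k not in ("prop", "mthi"):
            errors.append(f"unknown gradient kind {k!r}")
    for s in config.scenarios:
        if s not in ("S1", "S2"):
            errors.append(f"unknown scenario {s!r}")
    if config.kinship not in ("A", "H"):
        errors.append(f"kinship must be 'A' or 'H', got {config.kinship!r}")
    if not (0.0 <= config.omega <= 1.0):
        errors.append("omega must be in [0, 1]")
    if not (0.0 <= config.accuracy_threshold <= 1.0):
        errors.append("accuracy threshold must be in [0, 1]")
    if not (0.0 < config.top_fraction <= 0.5):
        errors.append("top fraction must be in (0, 0.5]")
    if config.simulate is None and config.paths is None:
        errors.append("either a simulate block or input paths must be given")
    if config.simulate is not None:
        try:
            config.sim_config()
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate block invalid: {exc}")
    if config.paths is not None:
        for key in ("pedigree", "genotypes", "weather", "phenotypes"):
            if key not in config.paths:
                errors.append(f"input path {key!r} missing")
            elif key != "genotypes" and not Path(config.paths[key]).exists():
                errors.append(f"input file for {key!r} does not exist")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Any stage failure raises with a stage-tagged message; artifacts
    written before the failure are retained in the output directory.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def write(name, fn):
        path = out / name
        fn(path)
        artifacts[name] = _sha256(path)
        return path

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    try:
        current = stage("inputs")
        if config.simulate is not None:
            sim = config.sim_config()
            ped, geno, snp_map, weather, records, truth = simulate_all(sim)
            write("pedigree.csv", lambda p: io.write_pedigree_csv(ped, p))
            write("weather.csv", lambda p: io.write_weather_csv(weather, p))
            write("records.csv", lambda p: io.write_phenotypes_csv(records, p))
            io.write_genotype_matrix(geno, snp_map, ped.ids, out / "genotypes")
            artifacts["genotypes.geno.csv"] = _sha256(out / "genotypes.geno.csv")
            artifacts["genotypes.map.csv"] = _sha256(out / "genotypes.map.csv")
            geno_ids = ped.ids
        else:
            ped = io.read_pedigree_csv(config.paths["pedigree"])
            weather = io.read_weather_csv(config.paths["weather"])
            records = io.read_phenotypes_csv(config.paths["phenotypes"])
            geno, snp_map, geno_ids = io.read_genotype_matrix(config.paths["genotypes"])

        current = stage("phenotypes")
        table, derive_report = derive_traits(records)
        table, edit_report = edit_filters(table)
        write("phenotypes.csv", lambda p: table.to_csv(p, index=False))
        write("edit_report.json", lambda p: p.write_text(json.dumps(
            {"derive": derive_report.as_dict(), "edit": edit_report.as_dict()}, indent=2)))

        current = stage("gradients")
        daily = daily_summaries(weather, thi_threshold=config.thi_threshold,
                                min_run_hours=config.min_run_hours)
        write("daily_thi.csv", lambda p: daily.to_csv(p))

        current = stage("qc")
        geno_qc, map_qc, kept_ids, qc_report = qc_genotypes(geno, snp_map, ids=geno_ids)
        write("qc_report.json", lambda p: p.write_text(json.dumps(qc_report.as_dict(), indent=2)))

        current = stage("kinship")
        if config.kinship == "H":
            kin = Kinship.single_step(ped, kept_ids, geno_qc, omega=config.omega)
        else:
            kin = Kinship.from_pedigree(ped)

        current = stage("fit")
        id_pos = {a: i for i, a in enumerate(kin.ids)}
        heifer_pos = np.asarray([id_pos[a] for a in table["heifer_id"]])
        fits = {}
        eg_store = {}
        for kind in config.eg_kinds:
            for scenario in config.scenarios:
                if scenario == "S1":
                    spec = EGSpec(kind, S1_WINDOW, thi_threshold=config.thi_threshold,
                                  min_run_hours=config.min_run_hours)
                    windows_used = {t: spec.window for t in config.traits}
                else:
                    windows_used = {}
                for trait in config.traits:
                    tag = f"{trait}_{kind}_{scenario}"
                    df = table.copy()
                    if scenario == "S2":
                        def fitter(x, _df=df, _trait=trait):
                            d = _df.assign(x=x)
                            return ReactionNormModel.from_dataframe(
                                d, _trait, "x", kin).fit(compute_se=False)
                        scan = scan_critical_period(
                            kind, candidate_windows(), daily,
                            df["first_service_date"], fitter,
                            spec_template=EGSpec(kind, S1_WINDOW,
                                                 thi_threshold=config.thi_threshold,
                                                 min_run_hours=config.min_run_hours),
                        )
                        write(f"scan_{tag}.csv", lambda p, s=scan: s.to_csv(p, index=False))
                        best = scan.iloc[0]
                        spec = EGSpec(kind, (int(best["start"]), int(best["end"])),
                                      thi_threshold=config.thi_threshold,
                                      min_run_hours=config.min_run_hours)
                        windows_used[trait] = spec.window
                    x = eg_values(spec, daily, df["first_service_date"])
                    df["x"] = x
                    eg_store[tag] = x
                    res = ReactionNormModel.from_dataframe(df, trait, "x", kin).fit()
                    fits[tag] = res
                    write(f"fit_{tag}.json", lambda p, r=res: io.write_fit_json(r, p))
                    sol = pd.DataFrame({"id": kin.ids, "a0": res.a0, "a1": res.a1})
                    write(f"solutions_{tag}.csv", lambda p, s=sol: s.to_csv(p, index=False))

        current = stage("diagnostics")
        for tag, res in fits.items():
            trait = tag.split("_")[0]
            fav = diagnostics.FAVORABLE_DIRECTION[trait]
            report = diagnostics.sire_overlap(
                res, eg_store[tag], ped, heifer_pos,
                min_daughters=config.min_daughters, favorable=fav)
            write(f"sire_overlap_{tag}.csv",
                  lambda p, r=report: r.table.to_csv(p, index=False))

        current = stage("gwas")
        if config.kinship == "H":
            gidx_ped = ped.index_of(kept_ids)
            from .kinship import A_submatrix, blend_tune_G, vanraden_G
            A22 = A_submatrix(ped, gidx_ped)
            G0, freqs, _ = vanraden_G(geno_qc)
            G, _ = blend_tune_G(G0, A22, omega=config.omega)
            pos = np.asarray([id_pos[a] for a in kept_ids])
            for tag, res in fits.items():
                trait, kind = tag.split("_")[0], tag.split("_")[1]
                eff = gwas.backsolve_snp_effects(
                    res.a0[pos], res.a1[pos], geno_qc, G, map_qc)
                scan_w = gwas.window_scan(
                    eff, geno_qc,
                    {"intercept": res.params.sigma_a0_sq, "slope": res.params.sigma_a1_sq},
                    top_frac=config.top_fraction,
                )
                write(f"windows_{tag}.csv",
                      lambda p, s=scan_w: s.table.to_csv(p, index=False))
                for term in ("intercept", "slope"):
                    reg = gwas.merge_regions(scan_w, term)
                    write(f"regions_{tag}_{term}.csv",
                          lambda p, r=reg: r.to_csv(p, index=False))
                grid = np.linspace(np.min(eg_store[tag]), np.max(eg_store[tag]), 11)
                clusters = gwas.cluster_trajectories(
                    eff, grid, top_frac=config.top_fraction,
                    favorable=diagnostics.FAVORABLE_DIRECTION[trait])
                write(f"clusters_{tag}.csv",
                      lambda p, c=clusters: c.summary.to_csv(p, index=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    config_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "run.log").write_text(json.dumps(
        {k: round(time.time() - v, 3) for k, v in timings.items()}, indent=2))
    return manifest
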