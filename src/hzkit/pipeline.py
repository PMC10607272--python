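"""End-to-end hybrid-zone analysis from a single run configuration.

Stage order: load -> filter -> ancestry (supervised q, two passes) ->
sub-dataset designation -> diagnostic markers -> hybrid classification ->
transect projection -> cline fitting + AICc selection -> neutral-diffusion
timing.  Every stage writes its artifact into the output directory and the
run ends with a machine-readable ``report.json`` (schema-versioned, carrying
a hash of the configuration) plus a human-readable summary.

The ancestry stage bootstraps parental reference pools from the metadata
population labels, estimates q, re-designates parentals by the strict
q-threshold rule (default > 0.98) and re-estimates q from the refined pools.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, cline, diffusion, geometry, genio, hybrids
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON or YAML on disk)."""

    genotypes: str
    metadata: str
    outdir: str
    baseline: str | None = None          # polyline TSV; None -> estimate from q
    filter_policy: genio.FilterPolicy = field(default_factory=genio.FilterPolicy)
    parental_threshold: float = 0.98     # q > threshold designates parentals
    pure_threshold: float = 0.90         # q > threshold counts as a pure individual
    diagnostic_min_n: int = 2
    classification_min_loci: int = 3
    cline_iterations: int = 100_000
    cline_burnin: float = 0.1
    cline_models: str | list[str] = "all"
    dispersal_km_per_year: float | None = None
    generation_time_years: float | None = None
    sigma: float | None = None           # overrides the per-year construction
    seed: int = 0

    def validate(self) -> None:
        for label, path in (("genotypes", self.genotypes), ("metadata", self.metadata)):
            if not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")
        if self.baseline is not None and not Path(self.baseline).exists():
            raise ConfigError(f"baseline file not found: {self.baseline}")
        if not (0.0 < self.cline_burnin <= 0.5):
            raise ConfigError("cline_burnin must be in (0, 0.5]")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for thr in (self.parental_threshold, self.pure_threshold):
            if not (0.5 < thr < 1.0):
                raise ConfigError("q thresholds must be in (0.5, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "filter_policy" in raw and isinstance(raw["filter_policy"], dict):
            raw["filter_policy"] = genio.FilterPolicy(**raw["filter_policy"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # output location is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _model_specs(config: RunConfig, likelihood: str) -> list[cline.ClineModelSpec]:
    if config.cline_models == "all":
        return cline.enumerate_models(likelihood)
    specs = []
    for name in config.cline_models:
        if name == "null":
            specs.append(cline.ClineModelSpec(likelihood=likelihood, is_null=True))
        else:
            scaling, tails = name.split("/")
            specs.append(cline.ClineModelSpec(scaling=scaling, tails=tails,
                                              likelihood=likelihood))
    return specs


def _fit_summary(best: cline.ClineFit) -> dict:
    return {
        "model": best.spec.name,
        "aicc": best.aicc,
        "loglik": best.loglik,
        "center_km": None if best.spec.is_null else round(best.params.center, 1),
        "width_km": None if best.spec.is_null else round(best.params.width, 1),
        "ci_center": list(best.ci_center) if best.ci_center else None,
        "ci_width": list(best.ci_width) if best.ci_width else None,
    }


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hzkit")
    root.addHandler(fh)
    root.setLevel(logging.INFO)

    report: dict = {"schema_version": SCHEMA_VERSION,
                    "config_hash": config.config_hash(),
                    "seed": config.seed, "stages": {}}
    stage = "load"
    try:
        gm = genio.read_genotypes(config.genotypes)
        meta = pd.read_csv(config.metadata, sep="\t", dtype={"sample": str})
        meta = meta.set_index("sample").loc[gm.samples].reset_index()
        log.info("loaded %d samples x %d loci", gm.n_samples, gm.n_loci)
        report["stages"][stage] = {"n_samples": gm.n_samples, "n_loci": gm.n_loci}

        stage = "filter"
        pops = pd.Series(meta["pop"].to_numpy(), index=meta["sample"])
        gm_f = genio.filter_variants(gm, pops, config.filter_policy)
        gm_f.to_tsv(out / "genotypes_filtered.tsv")
        log.info("filters retained %d / %d loci", gm_f.n_loci, gm.n_loci)
        report["stages"][stage] = {"n_loci_kept": gm_f.n_loci}

        stage = "ancestry"
        pop_names = sorted(pops.unique())
        if len(pop_names) != 2:
            raise ConfigError(f"need exactly 2 population labels, got {pop_names}")
        pool_a = [s for s, p in pops.items() if p == pop_names[0]]
        pool_b = [s for s, p in pops.items() if p == pop_names[1]]
        fa = ancestry.parental_allele_freqs(gm_f, pool_a)
        fb = ancestry.parental_allele_freqs(gm_f, pool_b)
        q0 = ancestry.estimate_q(gm_f, fa, fb).q_series()
        par_a, par_b, _ = ancestry.designate_parentals(q0, config.parental_threshold)
        if len(par_a) >= 2 and len(par_b) >= 2:
            # refine the reference pools with the strict parental designation
            fa = ancestry.parental_allele_freqs(gm_f, par_a)
            fb = ancestry.parental_allele_freqs(gm_f, par_b)
            result = ancestry.estimate_q(gm_f, fa, fb)
        else:
            log.warning("too few strict parentals (%d, %d); keeping "
                        "population-label reference pools", len(par_a), len(par_b))
            result = ancestry.estimate_q(gm_f, fa, fb)
        result.to_tsv(out / "q_values.tsv")
        q = result.q_series()
        par_a, par_b, admixed = ancestry.designate_parentals(q, config.parental_threshold)
        pure_a, pure_b, between = ancestry.designate_parentals(q, config.pure_threshold)
        log.info("designated %d parental-A, %d parental-B, %d admixed "
                 "(parental q threshold %.2f)", len(par_a), len(par_b),
                 len(admixed), config.parental_threshold)
        report["stages"][stage] = {
            "n_parental_a": len(par_a), "n_parental_b": len(par_b),
            "n_admixed": len(admixed),
            "n_pure_a": len(pure_a), "n_pure_b": len(pure_b),
            "pure_threshold": config.pure_threshold,
        }

        stage = "diagnostics"
        if len(par_a) < 2 or len(par_b) < 2:
            raise StageError(stage, "fewer than 2 parental individuals per side")
        panel = genio.select_diagnostic(gm_f, par_a, par_b, config.diagnostic_min_n)
        panel.to_tsv(out / "diagnostic_loci.tsv")
        log.info("selected %d diagnostic loci", len(panel))
        report["stages"][stage] = {"n_diagnostic": len(panel)}

        stage = "hybrid_classes"
        profiles = hybrids.classify_profiles(gm_f, panel, config.classification_min_loci)
        profiles.to_tsv(out / "hybrid_profiles.tsv")
        counts = profiles.class_counts().to_dict()
        report["stages"][stage] = {"class_counts": counts}

        stage = "transect"
        coords = meta[["lon", "lat"]].to_numpy()
        if config.baseline is not None:
            baseline = geometry.Baseline.from_tsv(config.baseline)
        else:
            baseline = geometry.estimate_baseline(coords, q.to_numpy(), crs="lonlat")
            log.info("baseline estimated from the ancestry surface "
                     "(logistic-contour substitute)")
        baseline.to_tsv(out / "baseline.tsv")
        dist = geometry.project_to_transect(coords, baseline, coords_crs="lonlat")
        pd.DataFrame({"sample": meta["sample"], "distance_km": dist}).to_csv(
            out / "transect_distances.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "baseline_source": "file" if config.baseline else "estimated",
            "distance_range_km": [float(dist.min()), float(dist.max())],
        }

        stage = "clines"
        settings = cline.MCMCSettings(iterations=config.cline_iterations,
                                      burnin_frac=config.cline_burnin)
        ss = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        cline_report = {}

        ds_q = cline.ClineDataset(dist, q.to_numpy(), trait_type="ancestry",
                                  sample_ids=list(q.index))
        ds_q.to_tsv(out / "cline_data_ancestry.tsv")
        fits = cline.fit_all(ds_q, settings, seed=seeds[0],
                             specs=_model_specs(config, "gaussian"))
        best_q = cline.select_best(fits)
        best_q.to_json(out / "cline_fit_ancestry.json")
        cline_report["ancestry"] = _fit_summary(best_q)

        best_mt = None
        if "haplogroup" in meta.columns and meta["haplogroup"].notna().all():
            hap = (meta["haplogroup"].astype(str) == "B").astype(float).to_numpy()
            ds_mt = cline.ClineDataset(dist, hap, trait_type="haplogroup",
                                       sample_ids=list(meta["sample"]))
            ds_mt.to_tsv(out / "cline_data_haplogroup.tsv")
            fits_mt = cline.fit_all(ds_mt, settings, seed=seeds[1],
                                    specs=_model_specs(config, "bernoulli"))
            best_mt = cline.select_best(fits_mt)
            best_mt.to_json(out / "cline_fit_haplogroup.json")
            cline_report["haplogroup"] = _fit_summary(best_mt)
        report["stages"][stage] = cline_report

        stage = "diffusion"
        sigma = config.sigma
        if sigma is None and config.dispersal_km_per_year and config.generation_time_years:
            sigma = diffusion.per_generation_dispersal(
                config.dispersal_km_per_year, config.generation_time_years)
        if sigma is not None and config.generation_time_years and not best_q.spec.is_null:
            t = diffusion.time_to_width(best_q.params.width, sigma,
                                        config.generation_time_years)
            report["stages"][stage] = t.to_dict()
        else:
            report["stages"][stage] = None

    except StageError:
        _write_report(out, report)
        raise
    except Exception as e:
        _write_report(out, report)
        raise StageError(stage, str(e)) from e
    finally:
        root.removeHandler(fh)
        fh.close()

    _write_report(out, report)
    _write_summary(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)


def _write_summary(out: Path, report: dict) -> None:
    lines = [f"hzkit run (config {report['config_hash']}, seed {report['seed']})"]
    st = report["stages"]
    if "clines" in st:
        for trait, s in st["clines"].items():
            if s["width_km"] is not None:
                lines.append(
                    f"{trait} cline: model {s['model']}, width "
                    f"{s['width_km']} km (95% CI {s['ci_width'][0]:.1f}-"
                    f"{s['ci_width'][1]:.1f}), centre {s['center_km']} km")
            else:
                lines.append(f"{trait} cline: no-cline (null) model selected")
    if "hybrid_classes" in st:
        lines.append("hybrid classes: " + ", ".join(
            f"{k}={v}" for k, v in sorted(st["hybrid_classes"]["class_counts"].items())))
    if st.get("diffusion"):
        d = st["diffusion"]
        lines.append(
            f"neutral diffusion: {d['width_km']:.1f} km reached in "
            f"{d['years_rounded']} years (sigma {d['sigma_km_per_gen']} km/gen)")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
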