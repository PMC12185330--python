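"""End-to-end orchestration: simulate → score → correlate → fit → mediate.

Produces registry-analysis-style CSV outputs:

* ``table1.csv`` — per-disorder lifetime prevalence and the correlation of the
  disorder FGRS with GAEA (product-moment on the continuous scores and
  tetrachoric after a median split, reported side by side);
* ``table2.csv`` — additive-hazards estimates (%-unit increase in cases per
  34 years per SD) for models A1/A2/B/C per disorder;
* ``table3.csv`` — the male-only mediation decomposition;
* ``grids.csv`` — model-C predicted 34-year rates over an FGRS grid at five
  GAEA levels (the fan-shape figure data);
* ``manifest.json`` + ``run.log`` — configuration echo, per-stage counts and
  content hashes of every output.

All randomness is funnelled through named substreams of one master seed, so a
rerun with the same configuration is hash-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aalen, mediation, scoring, tetrachoric
from .pedigree import attach_cohab_years, relative_links
from .simulate import (
    DISORDER_CODES,
    RegistryBundle,
    SimulationConfig,
    founder_couples_for_cohort,
    read_bundle,
    simulate_population,
    write_bundle,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "links", "scores", "table1", "table2", "mediate", "grids")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "pedrisk_run"
    bundle_dir: str | Path | None = None  # read an existing bundle instead of simulating
    target_cohort: int = 100_000
    disorders: tuple[str, ...] = DISORDER_CODES
    models: tuple[str, ...] = ("A1", "A2", "B", "C")
    mediation_disorders: tuple[str, ...] = ("MD", "AD", "DUD", "AUD", "ADHD")
    sex: str = "all"  # all | F | M
    cohort_split: bool = False  # rerun table2 on the 1973-1983 / 1984-1995 halves
    seed: int = 0
    n_boot_hazard: int = 50
    n_boot_mediation: int = 200
    write_bundle_csv: bool = False
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model required")
        bad = [m for m in self.models if m not in aalen.MODEL_COVARIATES]
        if bad:
            raise ValueError(f"unknown models: {bad}")
        if self.sex not in ("all", "F", "M"):
            raise ValueError("sex must be all, F or M")


@dataclass
class RunManifest:
    config: dict
    stage_counts: dict[str, dict] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)
    log_path: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


def prevalence_summary(bundle: RegistryBundle, disorders=DISORDER_CODES) -> pd.DataFrame:
    """Lifetime prevalence per disorder: persons with >= 1 event / cohort size, in %.

    A person with several recorded events for the same disorder counts once.
    """
    n = len(bundle.persons)
    rows = []
    for code in disorders:
        cases = bundle.events.loc[bundle.events["disorder"] == code, "id"].nunique()
        rows.append(
            {"disorder": code, "cases": cases, "n": n, "prevalence_pct": 100.0 * cases / n}
        )
    return pd.DataFrame(rows)


def lifetime_prevalence_pct(cases: int, n: int) -> float:
    """Lifetime prevalence as the percentage of the cohort ever registered."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    return 100.0 * cases / n


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage, writing tables and a manifest to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pedrisk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config={
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        log_path=str(log_path),
    )
    stage = "simulate"
    try:
        t0 = _time.time()
        if config.bundle_dir is not None:
            bundle = read_bundle(config.bundle_dir)
        else:
            sim_cfg = config.simulation
            if sim_cfg is None:
                sim_cfg = SimulationConfig(
                    n_founder_couples=founder_couples_for_cohort(config.target_cohort),
                    seed=seeds["simulate"],
                )
            bundle = simulate_population(sim_cfg)
        cohort_mask = bundle.cohort_mask(
            (config.simulation or SimulationConfig()).birth_year_range
        )
        cohort_ids = bundle.persons.loc[cohort_mask, "id"].to_numpy(np.int64)
        cohort = RegistryBundle(
            persons=bundle.persons[cohort_mask].reset_index(drop=True),
            pedigree=bundle.pedigree,
            events=bundle.events,
            cohab=bundle.cohab,
        )
        if config.write_bundle_csv:
            write_bundle(bundle, outdir / "bundle")
        manifest.stage_counts[stage] = {
            "persons": len(bundle.persons),
            "cohort": len(cohort_ids),
            "events": len(bundle.events),
            "seconds": round(_time.time() - t0, 2),
        }
        logger.info("simulate: %d persons, %d cohort", len(bundle.persons), len(cohort_ids))

        stage = "links"
        t0 = _time.time()
        links = relative_links(bundle.pedigree, probands=cohort_ids)
        links = attach_cohab_years(links, bundle.cohab)
        manifest.stage_counts[stage] = {
            "links": len(links),
            "mean_relatives": round(len(links) / max(len(cohort_ids), 1), 2),
            "seconds": round(_time.time() - t0, 2),
        }
        logger.info("links: %d (mean %.1f per proband)", len(links),
                    len(links) / max(len(cohort_ids), 1))

        stage = "scores"
        t0 = _time.time()
        scores = scoring.compute_all_scores(
            bundle, links, list(config.disorders), probands=cohort_ids
        )
        manifest.stage_counts[stage] = {
            "scored": len(scores),
            "seconds": round(_time.time() - t0, 2),
        }

        stage = "table1"
        t0 = _time.time()
        prev = prevalence_summary(
            RegistryBundle(
                persons=cohort.persons,
                pedigree=bundle.pedigree,
                events=bundle.events[bundle.events["id"].isin(cohort_ids)],
                cohab=bundle.cohab,
            ),
            config.disorders,
        )
        t1_rows = []
        for code in config.disorders:
            a = scores[f"FGRS_{code}"].to_numpy()
            b = scores["GAEA"].to_numpy()
            pm = tetrachoric.score_correlation(a, b, method="product-moment")
            tc = tetrachoric.score_correlation(a, b, method="tetrachoric")
            p = prev.loc[prev["disorder"] == code].iloc[0]
            t1_rows.append(
                {
                    "disorder": code,
                    "cases": int(p["cases"]),
                    "n": int(p["n"]),
                    "prevalence_pct": p["prevalence_pct"],
                    "corr_product_moment": pm.rho,
                    "se_product_moment": pm.se,
                    "corr_tetrachoric": tc.rho,
                    "se_tetrachoric": tc.se,
                }
            )
        table1 = pd.DataFrame(t1_rows)
        _write_csv(table1, outdir / "table1.csv")
        manifest.stage_counts[stage] = {"rows": len(table1), "seconds": round(_time.time() - t0, 2)}

        stage = "table2"
        t0 = _time.time()
        table2 = _fit_table2(cohort, scores, config, seeds["table2"])
        _write_csv(table2, outdir / "table2.csv")
        manifest.stage_counts[stage] = {"rows": len(table2), "seconds": round(_time.time() - t0, 2)}
        if config.cohort_split:
            for span in ((1973, 1983), (1984, 1995)):
                sub = _fit_table2(cohort, scores, config, seeds["table2"], cohort_years=span)
                _write_csv(sub, outdir / f"table2_{span[0]}_{span[1]}.csv")

        stage = "mediate"
        t0 = _time.time()
        table3 = _fit_table3(cohort, scores, config, seeds["mediate"])
        _write_csv(table3, outdir / "table3.csv")
        manifest.stage_counts[stage] = {"rows": len(table3), "seconds": round(_time.time() - t0, 2)}

        stage = "grids"
        t0 = _time.time()
        grids = _prediction_grids(cohort, scores, config)
        _write_csv(grids, outdir / "grids.csv")
        manifest.stage_counts[stage] = {"rows": len(grids), "seconds": round(_time.time() - t0, 2)}
    except Exception as exc:  # partial manifest travels with the failure
        _finalize_manifest(manifest, outdir)
        root.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc, manifest) from exc

    _finalize_manifest(manifest, outdir)
    root.removeHandler(handler)
    handler.close()
    return manifest


def _finalize_manifest(manifest: RunManifest, outdir: Path) -> None:
    for p in sorted(outdir.glob("*.csv")):
        manifest.output_hashes[p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(manifest.to_json())


def _fit_table2(
    cohort: RegistryBundle,
    scores: pd.DataFrame,
    config: RunConfig,
    seed: int,
    cohort_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    rows = []
    sex_filter = None if config.sex == "all" else config.sex
    for code in config.disorders:
        for model in config.models:
            try:
                design = aalen.build_design(
                    cohort, scores, code, model=model,
                    sex_filter=sex_filter, cohort_years=cohort_years,
                )
                summary = aalen.summarize_34y(
                    design, n_boot=config.n_boot_hazard, seed=seed
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.info("table2: skipping %s model %s (%s)", code, model, exc)
                continue
            for term, est, lo, hi in zip(
                summary.columns, summary.estimate, summary.ci_low, summary.ci_high
            ):
                rows.append(
                    {
                        "disorder": code,
                        "model": model,
                        "term": term,
                        "estimate": est,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n": len(design.time),
                        "events": int(design.event.sum()),
                    }
                )
    return pd.DataFrame(rows)


def _fit_table3(
    cohort: RegistryBundle, scores: pd.DataFrame, config: RunConfig, seed: int
) -> pd.DataFrame:
    decomps: dict[str, mediation.MediationDecomposition] = {}
    pvals: dict[str, float] = {}
    for i, code in enumerate(config.mediation_disorders):
        try:
            inp = mediation.mediation_input_from_bundle(cohort, scores, code)
            decomps[code] = mediation.fit_paths(inp)
            pvals[code] = mediation.iq_vs_resilience_test(
                inp, n_boot=config.n_boot_mediation, seed=seed + i
            )
        except (ValueError, RuntimeError) as exc:
            logger.info("table3: skipping %s (%s)", code, exc)
    table = mediation.proportion_table(decomps)
    if not table.empty:
        table["p_iq_vs_res"] = table["disorder"].map(pvals)
    return table


def _prediction_grids(
    cohort: RegistryBundle, scores: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    frames = []
    sex_filter = None if config.sex == "all" else config.sex
    for code in config.disorders:
        try:
            design = aalen.build_design(cohort, scores, code, model="C", sex_filter=sex_filter)
            fit = aalen.fit_aalen(design)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.info("grids: skipping %s (%s)", code, exc)
            continue
        grid = aalen.prediction_grid(fit)
        grid.insert(0, "disorder", code)
        grid.insert(1, "sex", config.sex)
        frames.append(grid)
    if not frames:
        return pd.DataFrame(columns=["disorder", "sex", "gaea_level", "fgrs", "predicted_rate"])
    return pd.concat(frames, ignore_index=True)
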