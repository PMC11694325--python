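"""End-to-end orchestration: generate -> ingest -> classify -> scan -> describe
-> risk factors, as one reproducible run with a manifest, plus the replicate
simulation harnesses used to measure the workflow's operating characteristics
(planted-effect recovery and null calibration).
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ALL_PPI_GROUP, STUDY_PPIS, __version__
from . import ingest, meddra, outcomes, riskmodel, signals
from .synthetic_faers import GeneratorConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Reproducibility metadata for one pipeline run."""

    config_sha256: str
    seed: int
    version: str
    started: str
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)

    def chain_consistent(self) -> bool:
        c = self.stage_counts
        return (
            c.get("ingest_in") == c.get("generated")
            and c.get("classified") == c.get("ingest_out")
            and c.get("tae_cases", 0) <= c.get("classified", 0)
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _config_from_mapping(raw: Mapping) -> GeneratorConfig:
    gen = dict(raw.get("generator", {}))
    if "association" in gen:
        gen["association"] = {
            (drug, pt): float(r) for drug, pt, r in gen["association"]
        }
    if "date_window" in gen:
        gen["date_window"] = tuple(
            dt.date.fromisoformat(str(d)) for d in gen["date_window"]
        )
    for key in ("drug_names", "event_vocabulary", "tumor_pts"):
        if key in gen and gen[key] is not None:
            gen[key] = tuple(gen[key])
    return GeneratorConfig(**gen)


def load_config(path) -> tuple[GeneratorConfig, dict]:
    """Parse the YAML run config into a generator config and run options."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    options = {
        "hierarchy": raw.get("hierarchy"),
        "min_cases": int(raw.get("scan", {}).get("min_cases", 3)),
        "z": float(raw.get("scan", {}).get("z", 1.96)),
        # Disproportionality needs the unexposed background, so the
        # suspect-role restriction is opt-in for full pipeline runs.
        "suspect_only": bool(raw.get("suspect_only", False)),
        "out": raw.get("out"),
    }
    return _config_from_mapping(raw), options


def run_all(config_path, out_dir=None, seed: int | None = None) -> RunManifest:
    """Run every stage from one config file; write outputs plus a manifest.

    Tabular outputs are byte-identical across reruns of the same config and
    seed; only the manifest timestamps differ.
    """
    started = dt.datetime.now().isoformat(timespec="seconds")
    config_text = Path(config_path).read_text()
    gen_config, options = load_config(config_path)
    if seed is not None:
        gen_config.seed = seed
    out = Path(out_dir or options["out"] or "pvdisprop_run")
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_sha256=hashlib.sha256(config_text.encode()).hexdigest(),
        seed=gen_config.seed,
        version=__version__,
        started=started,
    )
    counts = manifest.stage_counts

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(
                        f"stage {name!r} failed: {exc}"
                    ) from exc

        return _Ctx()

    with stage("generate"):
        records = generate_dataset(gen_config)
        counts["generated"] = len(records)
        write_dataset(records, out / "raw")

    with stage("ingest"):
        raw = ingest.read_dataset(out / "raw")
        counts["ingest_in"] = len(raw)
        cases, ledger = ingest.run(raw, suspect_only=options["suspect_only"])
        counts["ingest_out"] = len(cases)
        (out / "filter_ledger.json").write_text(json.dumps(ledger.as_dict(), indent=2))

    with stage("classify"):
        hierarchy = (
            meddra.load_hierarchy(options["hierarchy"])
            if options["hierarchy"]
            else meddra.default_hierarchy()
        )
        if len(hierarchy) == 0:
            raise ValueError("hierarchy is empty")
        classification = meddra.classify_cases(cases, hierarchy)
        counts["classified"] = classification.n_cases
        counts["tae_cases"] = classification.n_tae
        case_frame = ingest.cases_to_frame(cases)
        case_frame["is_tae"] = list(classification.is_tae)
        case_frame["matched_tae"] = [";".join(m) for m in classification.matched]
        case_frame.to_csv(out / "cases.tsv", sep="\t", index=False)

    with stage("scan"):
        results = signals.scan_all(
            cases,
            hierarchy,
            min_cases=options["min_cases"],
            z=options["z"],
        )
        counts["scanned_pairs"] = len(results)
        counts["signals"] = sum(r.is_signal for r in results)
        signals.results_frame(results).to_csv(out / "signals.tsv", sep="\t", index=False)
        mat = signals.ror_matrix(results)
        if not mat.empty:
            mat.to_csv(out / "ror_matrix.tsv", sep="\t")

    with stage("describe"):
        tae_cases = [cases[i] for i in classification.tae_indices()]
        if tae_cases:
            table1 = outcomes.summarize_table1(tae_cases)
            table1.frame().to_csv(out / "table1.tsv", sep="\t", index=False)
            outcomes.tumor_site_profile(tae_cases, hierarchy).to_csv(
                out / "tumor_sites.tsv", sep="\t", index=False
            )
            co = outcomes.co_reported_profile(tae_cases, hierarchy)
            co.soc_table.to_csv(out / "co_reported_soc.tsv", sep="\t", index=False)
            co.pt_table.to_csv(out / "co_reported_pt.tsv", sep="\t", index=False)
            for group_by in ("fatal", "group"):
                tto, _ = outcomes.time_to_onset_frame(tae_cases, group_by=group_by)
                if tto.empty or tto["group"].nunique() < 2:
                    continue
                km = outcomes.km_curve(tto)
                km_frames = [
                    curve.frame().assign(group=label)
                    for label, curve in km.curves.items()
                ]
                pd.concat(km_frames).to_csv(
                    out / f"km_{group_by}.tsv", sep="\t", index=False
                )
        outcomes.annual_proportions(cases, classification.is_tae).to_csv(
            out / "annual_proportions.tsv", sep="\t", index=False
        )

    with stage("riskfactors"):
        frame = riskmodel.build_model_frame(cases, classification)
        fits = list(riskmodel.standard_fits(frame).values())
        fits += riskmodel.dose_subgroups(frame)
        if fits:
            riskmodel.fits_frame(fits).to_csv(
                out / "risk_factors.tsv", sep="\t", index=False
            )

    manifest.finished = dt.datetime.now().isoformat(timespec="seconds")
    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# Operating-characteristics harnesses (replicate simulations).


def _chain(config: GeneratorConfig):
    """generate -> dedup/exclusions -> classify, returning cases + hierarchy."""
    records = generate_dataset(config)
    cases, _ = ingest.run(records)
    hierarchy = meddra.default_hierarchy()
    classification = meddra.classify_cases(cases, hierarchy)
    return cases, hierarchy, classification


def recovery_study(
    target_rors: Sequence[float] = (2.0, 5.0, 10.0),
    n_cases: int = 100_000,
    n_seeds: int = 50,
    base_seed: int = 0,
    drug: str = "esomeprazole",
    event: str = "Gastric cancer",
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Planted-effect recovery: per seed and target, the estimated ROR for the
    planted (drug, event) pair and whether the scan flagged it as a signal.
    """
    template = config or GeneratorConfig()
    rows = []
    for target in target_rors:
        for k in range(n_seeds):
            cfg = GeneratorConfig(
                **{
                    **template.__dict__,
                    "n_cases": n_cases,
                    "seed": int(base_seed) + k,
                    "association": {(drug, event): float(target)},
                }
            )
            cases, hierarchy, _ = _chain(cfg)
            table = signals.build_table(
                cases, (drug,), event, drug_group_label=drug
            )
            result = signals.compute_ror(table)
            rows.append(
                {
                    "target": target,
                    "seed": cfg.seed,
                    "estimate": result.ror,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "flagged": result.is_signal,
                    "n_cases_used": len(cases),
                }
            )
    return pd.DataFrame(rows)


def null_calibration(
    n_cases: int = 50_000,
    n_seeds: int = 200,
    base_seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """All-null calibration: per scanned (drug group, tumor PT) pair, the CI
    coverage of the null ROR 1.0 and the flagged-signal fraction across seeds.
    """
    template = config or GeneratorConfig()
    covered: dict[tuple[str, str], int] = {}
    seen: dict[tuple[str, str], int] = {}
    flagged: dict[tuple[str, str], int] = {}
    for k in range(n_seeds):
        cfg = GeneratorConfig(
            **{
                **template.__dict__,
                "n_cases": n_cases,
                "seed": int(base_seed) + k,
                "association": {},
            }
        )
        cases, hierarchy, _ = _chain(cfg)
        for r in signals.scan_all(cases, hierarchy):
            key = (r.drug_group, r.event)
            seen[key] = seen.get(key, 0) + 1
            if r.ci_low <= 1.0 <= r.ci_high:
                covered[key] = covered.get(key, 0) + 1
            if r.is_signal:
                flagged[key] = flagged.get(key, 0) + 1
    return pd.DataFrame(
        [
            {
                "drug_group": d,
                "event": e,
                "n_seeds": seen[(d, e)],
                "coverage": covered.get((d, e), 0) / seen[(d, e)],
                "signal_fraction": flagged.get((d, e), 0) / n_seeds,
            }
            for d, e in sorted(seen)
        ]
    )
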