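"""End-to-end orchestration of the instrument-development workflow.

Stage order mirrors the development procedure: (optional) simulation ->
item deletion -> multitrait scaling (with optional user-accepted
rescaling) -> Rasch partial credit fit -> scoring/reliability ->
validity.  Every stage writes delimited text so runs diff cleanly, and a
run manifest records the seed, configuration hash and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (AnalysisConfig, InstrumentDefinition, ResponseMatrix,
                   read_config, read_instrument, read_responses,
                   write_instrument, write_responses)
from .rasch import FitConfig, fit_pcm_from_matrix, wright_map
from .reduction import run_deletion_algorithm
from .scaling import classify_cells, item_domain_matrix, propose_rescaling
from .scoring import reliability_report, validity_report
from .simulate import (default_analysis_config, default_cohort_spec,
                       generate_cohort, write_ground_truth)

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    input_digests: dict
    outputs: dict
    started: str
    finished: str
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def cohort_summary(matrix: ResponseMatrix) -> pd.DataFrame:
    """Descriptive table of respondent covariates (n, mean, sd, range or
    category counts)."""
    rows = [{"variable": "respondents", "n": matrix.n, "summary": ""}]
    for col in matrix.covariates.columns:
        v = matrix.covariates[col]
        if v.dropna().empty:
            continue
        if pd.api.types.is_numeric_dtype(v):
            obs = v.dropna().astype(float)
            sd = obs.std(ddof=1) if len(obs) > 1 else 0.0
            rows.append({
                "variable": col, "n": int(len(obs)),
                "summary": (f"{obs.mean():.1f} +/- {sd:.1f} "
                            f"(range {obs.min():g} - {obs.max():g})"),
            })
        else:
            counts = v.dropna().value_counts()
            rows.append({
                "variable": col, "n": int(counts.sum()),
                "summary": "; ".join(f"{k}: {c}" for k, c in counts.items()),
            })
    return pd.DataFrame(rows)


def run_all(out_dir, responses_path=None, instrument_path=None,
            seed: int = 0, n_respondents: int = 69,
            accepted_moves: dict | None = None) -> RunManifest:
    """Run every stage, writing all reports under ``out_dir``.

    Without ``responses_path`` a default synthetic cohort is simulated
    first.  ``accepted_moves`` (item -> new domain) applies user-accepted
    rescaling proposals before the Rasch and validity stages.
    """
    started = datetime.now(timezone.utc).isoformat()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    digests: dict[str, str] = {}

    stage = "load"
    try:
        if responses_path is None:
            stage = "simulate"
            spec = default_cohort_spec(n_respondents=n_respondents, seed=seed)
            matrix, truth = generate_cohort(spec)
            instrument = spec.instrument()
            config = default_analysis_config(seed=seed)
            write_responses(matrix, out / "responses.csv")
            write_instrument(instrument, out / "instrument.yaml", config)
            write_ground_truth(truth, out / "ground_truth.csv")
            outputs["responses"] = "responses.csv"
            outputs["instrument"] = "instrument.yaml"
            outputs["ground_truth"] = "ground_truth.csv"
        else:
            if instrument_path is None:
                raise ValueError("instrument_path required with responses_path")
            instrument = read_instrument(instrument_path)
            config = read_config(instrument_path)
            matrix = read_responses(responses_path, instrument)
            digests[str(responses_path)] = _digest(Path(responses_path))
            digests[str(instrument_path)] = _digest(Path(instrument_path))

        stage = "summary"
        cohort_summary(matrix).to_csv(out / "cohort_summary.csv", index=False)
        outputs["summary"] = "cohort_summary.csv"

        stage = "reduce"
        report = run_deletion_algorithm(matrix, instrument, config)
        report.to_frame().to_csv(out / "deletion_report.csv", index=False)
        survivors = instrument.subset(report.retained_ids())
        write_instrument(survivors, out / "instrument_reduced.yaml", config)
        outputs["deletion_report"] = "deletion_report.csv"
        outputs["instrument_reduced"] = "instrument_reduced.yaml"

        stage = "scale"
        scaling = classify_cells(
            item_domain_matrix(matrix.subset_items(survivors.item_ids),
                               survivors, config=config), config)
        scaling.to_frame().to_csv(out / "scaling_matrix.csv", index=False)
        proposals = propose_rescaling(scaling)
        pd.DataFrame([p.__dict__ for p in proposals]).to_csv(
            out / "rescaling_proposals.csv", index=False)
        outputs["scaling_matrix"] = "scaling_matrix.csv"
        outputs["rescaling_proposals"] = "rescaling_proposals.csv"
        if accepted_moves:
            survivors = survivors.reassign(accepted_moves)

        stage = "rasch"
        fit = fit_pcm_from_matrix(matrix, survivors.item_ids, FitConfig())
        fit.item_table().to_csv(out / "rasch_items.csv", index=False)
        fit.person_table().to_csv(out / "rasch_persons.csv", index=False)
        witems, wpersons, wsummary = wright_map(fit, survivors)
        witems.to_csv(out / "wright_items.csv", index=False)
        wpersons.to_csv(out / "wright_persons.csv", index=False)
        outputs.update(rasch_items="rasch_items.csv",
                       rasch_persons="rasch_persons.csv",
                       wright_items="wright_items.csv",
                       wright_persons="wright_persons.csv")

        stage = "score"
        rel = reliability_report(matrix, survivors, config)
        rel.to_csv(out / "reliability.csv", index=False)
        outputs["reliability"] = "reliability.csv"

        stage = "validate"
        val = validity_report(matrix, survivors, config)
        val["external"].to_csv(out / "external_correlations.csv", index=False)
        rows = []
        for scale, rep in val["oxygen"].items():
            if rep is None:
                continue
            rows.append({"scale": scale, "mean_ever": rep.mean[0],
                         "mean_never": rep.mean[1], "difference": rep.difference,
                         "pooled_sd": rep.pooled_sd, "sdu": rep.sdu, "p": rep.p})
        pd.DataFrame(rows).to_csv(out / "oxygen_groups.csv", index=False)
        rows = []
        for scale, rep in val["tertiles"].items():
            if rep is None:
                continue
            rows.append({"scale": scale, "f": rep.f_stat, "p": rep.f_p,
                         "low_mean": rep.group_mean[0],
                         "high_mean": rep.group_mean[2],
                         "contrast_p": rep.contrast_p})
        pd.DataFrame(rows).to_csv(out / "tertile_contrasts.csv", index=False)
        outputs.update(external="external_correlations.csv",
                       oxygen="oxygen_groups.csv",
                       tertiles="tertile_contrasts.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    manifest = RunManifest(
        seed=seed, config_hash=config_hash, input_digests=digests,
        outputs=outputs, started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest
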