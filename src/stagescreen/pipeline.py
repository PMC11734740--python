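"""Orchestration of the staggered screen workflow.

Stage order mirrors the screen design: the primary SASP screen (B-scores,
fixed thresholds, both replicates) shortlists dual IL-6/IL-8 superinducer
genes; the secondary deconvolution screen (per-siRNA NPA over four SASP
channels) validates them; the killing-library selection picks multi-channel
hits plus capped CCL2-only candidates; and the NK-killing screen calls the
final enhancers.  Each stage reads/writes the canonical tidy CSVs of
:mod:`stagescreen.io` and every run emits a manifest (config snapshot,
input digests, counts) so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .hit_calling import (HitCallingConfig, call_killing_hits, call_primary_hits,
                          call_secondary_hits, select_killing_library)
from .io import PlateMeasurementSet, read_plate_table, write_hit_tables
from .normalization import MAD_GAUSSIAN, BScoreNormalizer, NPAScorer, aggregate_bscores

__all__ = ["RunManifest", "score_bscore_tier", "score_npa_tier", "run_staggered"]

log = logging.getLogger("stagescreen")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    input_digests: dict[str, str]
    version: str
    seeds: list[int] = field(default_factory=list)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def score_bscore_tier(pms: PlateMeasurementSet, *, max_iter: int = 100,
                      tol: float = 1e-6, mad_constant: float = MAD_GAUSSIAN
                      ) -> tuple[pd.DataFrame, BScoreNormalizer]:
    """B-score a tier and aggregate to one score per (siRNA, replicate, channel)."""
    norm = BScoreNormalizer(max_iter=max_iter, tol=tol, mad_constant=mad_constant)
    wells = norm.fit(pms).transform(pms)
    samples = wells[wells["role"] == "sample"]
    scores = aggregate_bscores(samples)
    return scores, norm


def score_npa_tier(pms: PlateMeasurementSet, *, clip: bool = False
                   ) -> tuple[pd.DataFrame, NPAScorer]:
    """NPA-score a tier against each plate's own controls and aggregate."""
    scorer = NPAScorer(per_plate=True, clip=clip)
    wells = scorer.fit(pms).transform(pms)
    samples = wells[wells["role"] == "sample"]
    scores = (
        samples.groupby(["gene", "sirna_id", "replicate", "channel"], dropna=False)["npa"]
        .mean().reset_index().rename(columns={"npa": "score"})
    )
    return scores, scorer


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text()) or {}
    return dict(config)


def _hit_config(cfg: dict) -> HitCallingConfig:
    return HitCallingConfig(**cfg.get("hit_calling", {}))


def run_staggered(config, input_dir, output_dir) -> RunManifest:
    """Run the requested tiers end to end and write all artifacts.

    ``config`` is a YAML path or mapping with optional keys ``tiers``
    (subset of primary/secondary/killing, in stage order), ``polish``,
    ``bscore``, ``npa``, ``hit_calling`` and ``killing_library``.  Inputs
    are ``<tier>.csv`` files in ``input_dir`` in the canonical schema.
    When both secondary and killing tiers run, the killing gene universe is
    restricted to the selected library; a standalone killing run analyses
    the provided library as-is.
    """
    cfg = _load_config(config)
    tiers = list(cfg.get("tiers", ["primary", "secondary", "killing"]))
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    hit_cfg = _hit_config(cfg)
    polish = cfg.get("polish", {})
    log.info("effective hit-calling config: %s", asdict(hit_cfg))

    manifest = RunManifest(config=cfg, input_digests={}, version=__version__,
                           started=datetime.datetime.now(datetime.UTC).isoformat())
    summary_lines: list[str] = []
    secondary_result = None
    secondary_scores = None
    library: list[str] | None = None

    for tier in tiers:
        path = input_dir / f"{tier}.csv"
        if not path.exists():
            raise FileNotFoundError(f"input for requested tier '{tier}' not found: {path}")
        manifest.input_digests[str(path.name)] = _digest(path)
        pms = read_plate_table(path)

        if tier == "primary":
            scores, _ = score_bscore_tier(
                pms, max_iter=polish.get("max_iter", 100), tol=polish.get("tol", 1e-6),
                mad_constant=cfg.get("bscore", {}).get("mad_constant", MAD_GAUSSIAN))
            result = call_primary_hits(scores, hit_cfg)
            hits_any = set().union(*result.per_channel_hits.values())
            summary_lines += [
                f"primary: {len(pms)} well measurements, "
                f"{scores['gene'].nunique()} genes scored",
                f"primary: IL6 hits {len(result.per_channel_hits.get('IL6', set()))}, "
                f"IL8 hits {len(result.per_channel_hits.get('IL8', set()))}, "
                f"dual hits {len(result.both)}",
            ]
            manifest.stage_counts["primary"] = {
                "records": len(pms), "genes": int(scores["gene"].nunique()),
                "il6_hits": len(result.per_channel_hits.get("IL6", set())),
                "il8_hits": len(result.per_channel_hits.get("IL8", set())),
                "dual_hits": len(result.both), "hits_any": len(hits_any)}
            tables = result.hit_tables
        elif tier == "secondary":
            scores, _ = score_npa_tier(pms, clip=cfg.get("npa", {}).get("clip", False))
            result = call_secondary_hits(scores, hit_cfg)
            secondary_result, secondary_scores = result, scores
            cap = cfg.get("killing_library", {}).get("cap_ccl2_only", 8)
            library = select_killing_library(result, scores, cap_ccl2_only=cap)
            pd.DataFrame({"gene": library}).to_csv(
                output_dir / "killing_library.csv", index=False)
            per_ch = {ch: len(g) for ch, g in result.channel_hits.items()}
            summary_lines += [
                f"secondary: {len(pms)} well measurements, "
                f"{scores['gene'].nunique()} genes scored",
                f"secondary: channel hits {per_ch}, validated {len(result.validated)}",
                f"secondary: killing library of {len(library)} genes selected",
            ]
            manifest.stage_counts["secondary"] = {
                "records": len(pms), "genes": int(scores["gene"].nunique()),
                "validated": len(result.validated), "library": len(library),
                **{f"{ch.lower()}_hits": n for ch, n in per_ch.items()}}
            tables = result.hit_tables
        elif tier == "killing":
            scores, _ = score_npa_tier(pms, clip=cfg.get("npa", {}).get("clip", False))
            restrict = cfg.get("killing", {}).get("restrict_to_library", "auto")
            if restrict == "auto":
                restrict = library is not None
            if restrict:
                if library is None:
                    raise RuntimeError(
                        "killing tier requested with library restriction but the "
                        "secondary tier did not run in this invocation")
                scores = scores[scores["gene"].isin(library)].reset_index(drop=True)
            result = call_killing_hits(scores, hit_cfg)
            summary_lines += [
                f"killing: {len(pms)} well measurements, "
                f"{scores['gene'].nunique()} genes scored",
                f"killing: {len(result.hits)} enhancer hits",
            ]
            manifest.stage_counts["killing"] = {
                "records": len(pms), "genes": int(scores["gene"].nunique()),
                "hits": len(result.hits)}
            tables = result.hit_tables
        else:
            raise ValueError(f"unknown tier {tier!r}")

        scores.to_csv(output_dir / f"{tier}_scores.csv", index=False,
                      float_format="%.12g")
        if tables:
            write_hit_tables(tables, output_dir / f"{tier}_hits.csv",
                             output_dir / f"{tier}_pass_matrix.csv")

    manifest.finished = datetime.datetime.now(datetime.UTC).isoformat()
    (output_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    manifest.to_json(output_dir / "manifest.json")
    return manifest
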