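"""Threshold + replicate-consensus hit calling for the three screen tiers.

The staggered screen calls hits with fixed score thresholds and consensus
rules rather than p-values:

* **primary** (pooled siRNAs, 2 replicates, B-scores): a gene is an IL-6
  hit iff both replicates have B >= 4.20, an IL-8 hit iff both have
  B >= 3.05; the dual-hit set is the intersection.  Thresholds correspond
  to the negative-control mean + 2 SD and can be recomputed from controls.
* **secondary** (4 siRNAs/gene, 3 replicates, NPA per channel): an siRNA
  qualifies for a channel iff NPA >= 1 (IL-6, IL-8) or NPA >= 2 (CCL2,
  IL-1B) in at least 2 of 3 replicates; a gene is a channel hit iff at
  least 2 siRNAs qualify, and "validated" iff it is a hit in >= 1 channel.
* **killing** (4 siRNAs/gene, 6 replicates, killing NPA): an siRNA
  qualifies iff NPA >= 0.7 in at least 3 of 6 replicates; a gene is a hit
  iff at least 2 siRNAs qualify.

All comparisons are inclusive (>=); missing scores never count as passes.
Score tables are tidy frames with columns gene, sirna_id, replicate,
channel, score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import HitTable

__all__ = [
    "HitCallingConfig",
    "PrimaryResult",
    "SecondaryResult",
    "KillingResult",
    "control_threshold",
    "call_primary_hits",
    "call_secondary_hits",
    "select_killing_library",
    "call_killing_hits",
    "PrimaryHitCaller",
    "SecondaryHitCaller",
    "KillingHitCaller",
]

SCORE_COLUMNS = ("gene", "sirna_id", "replicate", "channel", "score")


@dataclass
class HitCallingConfig:
    """Thresholds and consensus minima for all three tiers."""

    primary_thresholds: dict[str, float] = field(
        default_factory=lambda: {"IL6": 4.20, "IL8": 3.05})
    secondary_npa_thresholds: dict[str, float] = field(
        default_factory=lambda: {"IL6": 1.0, "IL8": 1.0, "CCL2": 2.0, "IL1B": 2.0})
    secondary_min_sirnas: int = 2
    secondary_min_reps: int = 2      # of 3
    killing_npa_threshold: float = 0.7
    killing_min_sirnas: int = 2      # of 4
    killing_min_reps: int = 3        # of 6
    control_sd_multiplier: float = 2.0
    max_sirnas_per_gene: int = 4
    secondary_consensus: str = "per-sirna"  # or "joint"

    def __post_init__(self) -> None:
        for name, thr in {**self.primary_thresholds,
                          **self.secondary_npa_thresholds,
                          "killing": self.killing_npa_threshold}.items():
            if not np.isfinite(thr):
                raise ValueError(f"non-finite threshold for {name}")
        if self.secondary_consensus not in {"per-sirna", "joint"}:
            raise ValueError(f"unknown secondary_consensus {self.secondary_consensus!r}")

    def with_overrides(self, **kwargs) -> "HitCallingConfig":
        return replace(self, **kwargs)


@dataclass
class PrimaryResult:
    il6_only: set[str]
    il8_only: set[str]
    both: set[str]
    per_channel_hits: dict[str, set[str]]
    hit_tables: list[HitTable]
    thresholds: dict[str, float]


@dataclass
class SecondaryResult:
    channel_hits: dict[str, set[str]]     # channel -> genes
    validated: set[str]                   # hit in >= 1 channel
    hit_tables: list[HitTable]
    thresholds: dict[str, float]


@dataclass
class KillingResult:
    hits: set[str]
    hit_tables: list[HitTable]
    threshold: float


def control_threshold(neg_scores, k: float = 2.0) -> float:
    """Hit threshold anchored on controls: mean + k x sample SD (ddof=1)."""
    x = np.asarray(neg_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 finite negative-control scores")
    return float(x.mean() + k * x.std(ddof=1))


def _score_tensor(block: pd.DataFrame, max_sirnas: int | None = None
                  ) -> tuple[np.ndarray, list[str], list[int]]:
    """(siRNA x replicate) score matrix for one gene/channel; NaN = missing."""
    sirnas = sorted(block["sirna_id"].unique())
    if max_sirnas is not None and len(sirnas) > max_sirnas:
        raise ValueError(
            f"gene {block['gene'].iloc[0]} has {len(sirnas)} siRNAs; "
            f"library contract allows at most {max_sirnas}")
    reps = sorted(block["replicate"].unique())
    mat = np.full((len(sirnas), len(reps)), np.nan)
    si = {s: i for i, s in enumerate(sirnas)}
    ri = {r: j for j, r in enumerate(reps)}
    for row in block.itertuples(index=False):
        mat[si[row.sirna_id], ri[row.replicate]] = row.score
    return mat, sirnas, [int(r) for r in reps]


def _consensus(passes: np.ndarray, min_sirnas: int, min_reps: int,
               mode: str = "per-sirna") -> bool:
    """Evaluate '>= min_sirnas siRNAs passing in >= min_reps replicates'.

    per-sirna: each qualifying siRNA must itself pass in >= min_reps
    replicates (the standard RNAi-screen reading).  joint: there must be
    >= min_reps replicates in which >= min_sirnas siRNAs pass together.
    """
    if mode == "per-sirna":
        return int((passes.sum(axis=1) >= min_reps).sum()) >= min_sirnas
    return int((passes.sum(axis=0) >= min_sirnas).sum()) >= min_reps


def call_primary_hits(
    scores: pd.DataFrame, cfg: HitCallingConfig | None = None
) -> PrimaryResult:
    """Call pooled-siRNA primary hits: both replicates >= the channel threshold.

    ``scores`` carries one pooled-siRNA B-score per (gene, replicate,
    channel); a gene with a missing replicate is not a hit.  The summary
    sets are disjoint (IL6-only excludes the dual hits) while the hit
    tables keep the raw per-channel calls.
    """
    cfg = cfg or HitCallingConfig()
    unknown = set(scores["channel"].unique()) - set(cfg.primary_thresholds)
    if unknown:
        raise ValueError(f"no primary threshold configured for channel(s) {sorted(unknown)}")

    per_channel: dict[str, set[str]] = {ch: set() for ch in cfg.primary_thresholds}
    tables: list[HitTable] = []
    for (gene, channel), block in scores.groupby(["gene", "channel"]):
        thr = cfg.primary_thresholds[channel]
        mat, sirnas, reps = _score_tensor(block)
        passes = np.nan_to_num(mat, nan=-np.inf) >= thr
        # pooled library: one siRNA pool per gene, every replicate must pass
        is_hit = bool(passes.all()) and mat.shape[1] >= 2 and not np.isnan(mat).any()
        if is_hit:
            per_channel[channel].add(gene)
        tables.append(HitTable(gene=gene, channel=channel, tier="primary",
                               is_hit=is_hit, pass_matrix=passes, score_matrix=mat,
                               threshold_used=thr, sirna_ids=sirnas,
                               replicate_ids=reps))

    il6, il8 = per_channel.get("IL6", set()), per_channel.get("IL8", set())
    both = il6 & il8
    return PrimaryResult(il6_only=il6 - both, il8_only=il8 - both, both=both,
                         per_channel_hits=per_channel, hit_tables=tables,
                         thresholds=dict(cfg.primary_thresholds))


def call_secondary_hits(
    npa_scores: pd.DataFrame, cfg: HitCallingConfig | None = None
) -> SecondaryResult:
    """Call secondary-screen hits per channel and the overall validated set."""
    cfg = cfg or HitCallingConfig()
    unknown = set(npa_scores["channel"].unique()) - set(cfg.secondary_npa_thresholds)
    if unknown:
        raise ValueError(f"no NPA threshold configured for channel(s) {sorted(unknown)}")

    channel_hits: dict[str, set[str]] = {ch: set() for ch in cfg.secondary_npa_thresholds}
    tables: list[HitTable] = []
    for (gene, channel), block in npa_scores.groupby(["gene", "channel"]):
        thr = cfg.secondary_npa_thresholds[channel]
        mat, sirnas, reps = _score_tensor(block, cfg.max_sirnas_per_gene)
        passes = np.nan_to_num(mat, nan=-np.inf) >= thr
        is_hit = _consensus(passes, cfg.secondary_min_sirnas, cfg.secondary_min_reps,
                            cfg.secondary_consensus)
        if is_hit:
            channel_hits[channel].add(gene)
        tables.append(HitTable(gene=gene, channel=channel, tier="secondary",
                               is_hit=is_hit, pass_matrix=passes, score_matrix=mat,
                               threshold_used=thr, sirna_ids=sirnas,
                               replicate_ids=reps))

    validated = set().union(*channel_hits.values()) if channel_hits else set()
    return SecondaryResult(channel_hits=channel_hits, validated=validated,
                           hit_tables=tables,
                           thresholds=dict(cfg.secondary_npa_thresholds))


def select_killing_library(
    secondary: SecondaryResult,
    npa_scores: pd.DataFrame | None = None,
    cap_ccl2_only: int = 8,
) -> list[str]:
    """Assemble the killing-screen library from secondary-screen calls.

    All genes that are hits in >= 2 of the 4 SASP channels enter, plus up
    to ``cap_ccl2_only`` genes whose only hit channel is CCL2 (CCL2 being
    an NK-cell chemoattractant).  CCL2-only genes are ranked by their best
    CCL2 NPA, ties broken alphabetically; ``npa_scores`` supplies the
    ranking and may be omitted when no cap applies.
    """
    hit_count: dict[str, int] = {}
    for genes in secondary.channel_hits.values():
        for g in genes:
            hit_count[g] = hit_count.get(g, 0) + 1

    multi = {g for g, n in hit_count.items() if n >= 2}
    ccl2_only = {g for g, n in hit_count.items()
                 if n == 1 and g in secondary.channel_hits.get("CCL2", set())}

    if len(ccl2_only) > cap_ccl2_only:
        if npa_scores is None:
            raise ValueError("npa_scores required to rank CCL2-only candidates")
        best = (npa_scores[(npa_scores["channel"] == "CCL2")
                           & npa_scores["gene"].isin(ccl2_only)]
                .groupby("gene")["score"].max())
        ranked = sorted(ccl2_only, key=lambda g: (-best.get(g, -np.inf), g))
        ccl2_picked = ranked[:cap_ccl2_only]
    else:
        ccl2_picked = sorted(ccl2_only)

    return sorted(multi) + ccl2_picked


def call_killing_hits(
    npa_scores: pd.DataFrame, cfg: HitCallingConfig | None = None
) -> KillingResult:
    """Call NK-killing hits: >= 2 of 4 siRNAs with NPA >= 0.7 in >= 3 of 6 reps."""
    cfg = cfg or HitCallingConfig()
    thr = cfg.killing_npa_threshold
    hits: set[str] = set()
    tables: list[HitTable] = []
    for gene, block in npa_scores.groupby("gene"):
        mat, sirnas, reps = _score_tensor(block, cfg.max_sirnas_per_gene)
        passes = np.nan_to_num(mat, nan=-np.inf) >= thr
        is_hit = _consensus(passes, cfg.killing_min_sirnas, cfg.killing_min_reps)
        if is_hit:
            hits.add(gene)
        tables.append(HitTable(gene=gene, channel="KILLING", tier="killing",
                               is_hit=is_hit, pass_matrix=passes, score_matrix=mat,
                               threshold_used=thr, sirna_ids=sirnas,
                               replicate_ids=reps))
    return KillingResult(hits=hits, hit_tables=tables, threshold=thr)


def verify_hit_table(table: HitTable, cfg: HitCallingConfig | None = None) -> bool:
    """Re-derive ``is_hit`` from the pass matrix under the tier's rule."""
    cfg = cfg or HitCallingConfig()
    p = table.pass_matrix
    if table.tier == "primary":
        rederived = bool(p.all()) and p.shape[1] >= 2 and not np.isnan(table.score_matrix).any()
    elif table.tier == "secondary":
        rederived = _consensus(p, cfg.secondary_min_sirnas, cfg.secondary_min_reps,
                               cfg.secondary_consensus)
    elif table.tier == "killing":
        rederived = _consensus(p, cfg.killing_min_sirnas, cfg.killing_min_reps)
    else:
        raise ValueError(f"unknown tier {table.tier!r}")
    return rederived == table.is_hit


# ---------------------------------------------------------------------------
# estimator wrappers


class _BaseHitCaller(BaseEstimator):
    """Shared fit/predict plumbing over a tidy score frame."""

    _tier: str = ""

    def _config(self) -> HitCallingConfig:  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y=None):
        self.config_ = self._config()
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Boolean hit flag per gene (any-channel for multi-channel tiers)."""
        result = self.call(X)
        genes = sorted(X["gene"].unique())
        if self._tier == "primary":
            hit = set().union(*result.per_channel_hits.values())
        elif self._tier == "secondary":
            hit = result.validated
        else:
            hit = result.hits
        return pd.Series([g in hit for g in genes], index=genes, name="is_hit")

    def call(self, X: pd.DataFrame):
        if not hasattr(self, "config_"):
            self.fit(X)
        return self._call(X)


class PrimaryHitCaller(_BaseHitCaller):
    """Primary-tier caller over pooled-siRNA B-scores.

    With ``from_controls=True`` the per-channel thresholds are recomputed
    during fit as mean + ``sd_multiplier`` x SD of the negative-control
    B-scores passed as ``controls`` (a channel -> scores mapping),
    mirroring how the printed fixed thresholds were derived.
    """

    _tier = "primary"

    def __init__(self, il6_threshold: float = 4.20, il8_threshold: float = 3.05,
                 from_controls: bool = False, sd_multiplier: float = 2.0):
        self.il6_threshold = il6_threshold
        self.il8_threshold = il8_threshold
        self.from_controls = from_controls
        self.sd_multiplier = sd_multiplier

    def _config(self) -> HitCallingConfig:
        return HitCallingConfig(
            primary_thresholds={"IL6": self.il6_threshold, "IL8": self.il8_threshold},
            control_sd_multiplier=self.sd_multiplier)

    def fit(self, X: pd.DataFrame, y=None, controls: dict[str, np.ndarray] | None = None):
        cfg = self._config()
        if self.from_controls:
            if controls is None:
                raise ValueError("from_controls=True requires negative-control scores")
            cfg = cfg.with_overrides(primary_thresholds={
                ch: control_threshold(v, self.sd_multiplier)
                for ch, v in controls.items()})
        self.config_ = cfg
        self.thresholds_ = dict(cfg.primary_thresholds)
        return self

    def _call(self, X: pd.DataFrame) -> PrimaryResult:
        return call_primary_hits(X, self.config_)


class SecondaryHitCaller(_BaseHitCaller):
    """Secondary-tier caller over per-siRNA NPA scores (4 channels)."""

    _tier = "secondary"

    def __init__(self, il6_threshold: float = 1.0, il8_threshold: float = 1.0,
                 ccl2_threshold: float = 2.0, il1b_threshold: float = 2.0,
                 min_sirnas: int = 2, min_reps: int = 2,
                 consensus: str = "per-sirna"):
        self.il6_threshold = il6_threshold
        self.il8_threshold = il8_threshold
        self.ccl2_threshold = ccl2_threshold
        self.il1b_threshold = il1b_threshold
        self.min_sirnas = min_sirnas
        self.min_reps = min_reps
        self.consensus = consensus

    def _config(self) -> HitCallingConfig:
        return HitCallingConfig(
            secondary_npa_thresholds={"IL6": self.il6_threshold,
                                      "IL8": self.il8_threshold,
                                      "CCL2": self.ccl2_threshold,
                                      "IL1B": self.il1b_threshold},
            secondary_min_sirnas=self.min_sirnas,
            secondary_min_reps=self.min_reps,
            secondary_consensus=self.consensus)

    def _call(self, X: pd.DataFrame) -> SecondaryResult:
        return call_secondary_hits(X, self.config_)


class KillingHitCaller(_BaseHitCaller):
    """Killing-tier caller over per-siRNA killing-NPA scores."""

    _tier = "killing"

    def __init__(self, npa_threshold: float = 0.7, min_sirnas: int = 2,
                 min_reps: int = 3):
        self.npa_threshold = npa_threshold
        self.min_sirnas = min_sirnas
        self.min_reps = min_reps

    def _config(self) -> HitCallingConfig:
        return HitCallingConfig(killing_npa_threshold=self.npa_threshold,
                                killing_min_sirnas=self.min_sirnas,
                                killing_min_reps=self.min_reps)

    def _call(self, X: pd.DataFrame) -> KillingResult:
        return call_killing_hits(X, self.config_)
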