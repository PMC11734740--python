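"""Synthetic screens and cocultures with known ground truth.

The generator emulates the structure the analysis pipeline assumes:
96-well plates carrying non-targeting negative controls, positive-control
siRNAs against known SASP regulators (EPRS, LPAR2, SIRT1, LGMN), additive
row/column spatial artifacts, batch offsets shared within a transfection
batch, well-level Gaussian noise, and spiked "hit" siRNAs with a
configurable activation effect.  Every sample well is built as

    value = baseline[channel] + spatial + batch + effect + noise

truncated to the valid range of its readout ([0, 100] for percent-positive
channels, [-100, inf) for the killing percent change).  The siRNA layout of
a plate is fixed across replicates (the same physical daughter plate is
transfected in each batch), while spatial artifacts, batch offsets and
noise are redrawn per physical plate.

All randomness flows from a single seed through per-plate substreams, so
identical configs give identical screens and plates are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import PlateMeasurementSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_coculture",
    "evaluate_recovery",
    "POSITIVE_CONTROL_GENES",
]

#: Known SASP regulators used as positive-control siRNAs on every plate.
POSITIVE_CONTROL_GENES = ("EPRS", "LPAR2", "SIRT1", "LGMN")


@dataclass
class SimulationConfig:
    """Screen-design and noise parameters for :func:`simulate_screen`.

    Defaults describe a scaled-down primary screen; the classmethods
    :meth:`primary`, :meth:`secondary` and :meth:`killing` give the three
    tier presets (readouts, library shape and replicate counts of each
    screen stage).
    """

    n_genes: int = 420
    sirnas_per_gene: int = 1           # 1 = pooled library, 4 = deconvoluted
    n_replicates: int = 2
    channels: tuple[str, ...] = ("IL6", "IL8")
    baseline: dict[str, float] = field(default_factory=lambda: {"IL6": 10.0, "IL8": 10.0})
    hit_fraction: float = 0.05
    effect_size: dict[str, float] = field(default_factory=lambda: {"IL6": 40.0, "IL8": 40.0})
    row_amp: float = 3.0
    col_amp: float = 3.0
    batch_sd: float = 1.0
    well_sd: float = 2.0
    n_neg_controls: int = 8
    n_pos_controls: int = 4
    pos_control_effect: float | dict[str, float] = 40.0
    n_rows: int = 8
    n_cols: int = 12
    n_plates: int | None = None        # derived from library size when None
    tier: str = "primary"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hit_fraction <= 1.0):
            raise ValueError("hit_fraction must lie in [0, 1]")
        for name in ("batch_sd", "well_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        set(map(self._pos_effect, self.channels))  # force early key errors

    def _pos_effect(self, channel: str) -> float:
        if isinstance(self.pos_control_effect, dict):
            return self.pos_control_effect[channel]
        return self.pos_control_effect

    @property
    def samples_per_plate(self) -> int:
        return self.n_rows * self.n_cols - self.n_neg_controls - self.n_pos_controls

    @property
    def plates_needed(self) -> int:
        return max(1, math.ceil(self.n_genes * self.sirnas_per_gene / self.samples_per_plate))

    def resolved_plates(self) -> int:
        n = self.n_plates if self.n_plates is not None else self.plates_needed
        if self.n_genes * self.sirnas_per_gene > n * self.samples_per_plate:
            raise ValueError(
                f"library of {self.n_genes * self.sirnas_per_gene} siRNAs exceeds "
                f"{n} plate(s) x {self.samples_per_plate} sample wells")
        return n

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- tier presets --------------------------------------------------
    @classmethod
    def primary(cls, **kwargs) -> "SimulationConfig":
        """Pooled druggable-genome stage: IL-6/IL-8, 2 replicates.

        The default library (420 genes) fills its plates exactly: sparse,
        partially filled plates degrade the median-polish MAD estimate,
        which real pre-plated libraries do not exhibit.
        """
        return cls(**kwargs)

    @classmethod
    def secondary(cls, **kwargs) -> "SimulationConfig":
        """Deconvoluted validation stage: 4 siRNAs/gene, 3 replicates, 4 SASP channels.

        Effects for CCL2/IL-1B are larger than the positive-control shift
        so that true hits clear the stricter NPA >= 2 cut.
        """
        defaults = dict(
            n_genes=156, sirnas_per_gene=4, n_replicates=3, tier="secondary",
            channels=("IL6", "IL8", "CCL2", "IL1B"),
            baseline={"IL6": 10.0, "IL8": 10.0, "CCL2": 10.0, "IL1B": 10.0},
            effect_size={"IL6": 40.0, "IL8": 40.0, "CCL2": 50.0, "IL1B": 50.0},
            pos_control_effect=20.0, hit_fraction=0.5)
        defaults.update(kwargs)
        return cls(**defaults)

    @classmethod
    def killing(cls, **kwargs) -> "SimulationConfig":
        """NK-coculture stage: 4 siRNAs/gene, 6 replicates, percent-change readout.

        Negative baseline reflects modest NK-mediated loss of non-perturbed
        senescent cells; enhancer siRNAs shift the change further down, and
        the positive control is a strong killing enhancer.
        """
        defaults = dict(
            n_genes=76, sirnas_per_gene=4, n_replicates=6, tier="killing",
            channels=("KILLING",), baseline={"KILLING": -10.0},
            effect_size={"KILLING": -50.0}, pos_control_effect=-60.0,
            hit_fraction=0.15)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Spiked-hit identities and per-well latent components of a simulation."""

    true_hits: dict[str, frozenset]     # channel -> genes carrying the effect
    genes: list[str]
    components: pd.DataFrame            # per (well, channel): latent parts

    def hits_any_channel(self) -> frozenset:
        if not self.true_hits:
            return frozenset()
        return frozenset().union(*self.true_hits.values())


def _truncate(values: np.ndarray, channel: str) -> np.ndarray:
    if channel == "KILLING":
        return np.maximum(values, -100.0)
    return np.clip(values, 0.0, 100.0)


def simulate_screen(cfg: SimulationConfig) -> tuple[PlateMeasurementSet, GroundTruth]:
    """Generate one full screen tier with known ground truth.

    Deterministic given ``cfg.seed``; see the module docstring for the
    generative model.  Each transfection replicate is one batch whose
    plates share a batch offset per channel.
    """
    n_plates = cfg.resolved_plates()
    root = np.random.SeedSequence(cfg.seed)
    # independent substreams: layout/truth, batch offsets, then one per physical plate
    children = root.spawn(2 + n_plates * cfg.n_replicates)
    layout_rng = np.random.default_rng(children[0])
    batch_rng = np.random.default_rng(children[1])
    plate_children = children[2:]

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    n_hits = int(round(cfg.hit_fraction * cfg.n_genes))
    hit_genes = set(layout_rng.choice(genes, size=n_hits, replace=False)) if n_hits else set()
    true_hits = {
        ch: frozenset(hit_genes) if cfg.effect_size.get(ch, 0.0) != 0.0 else frozenset()
        for ch in cfg.channels
    }

    # physical layout, fixed across replicates: control positions + siRNA order
    n_wells = cfg.n_rows * cfg.n_cols
    sirnas = [(g, f"{g}-s{k + 1}") for g in genes for k in range(cfg.sirnas_per_gene)]
    layouts = []       # per plate: list of (row, col, role, gene, sirna_id)
    cursor = 0
    for p in range(n_plates):
        control_pos = layout_rng.choice(n_wells, size=cfg.n_neg_controls + cfg.n_pos_controls,
                                        replace=False)
        neg_pos = set(control_pos[:cfg.n_neg_controls].tolist())
        pos_pos = control_pos[cfg.n_neg_controls:].tolist()
        pos_gene = {w: POSITIVE_CONTROL_GENES[i % len(POSITIVE_CONTROL_GENES)]
                    for i, w in enumerate(pos_pos)}
        wells = []
        for w in range(n_wells):
            r, c = divmod(w, cfg.n_cols)
            if w in neg_pos:
                wells.append((r, c, "negative_control", None, "NT"))
            elif w in pos_gene:
                g = pos_gene[w]
                wells.append((r, c, "positive_control", g, f"si{g}"))
            elif cursor < len(sirnas):
                g, s = sirnas[cursor]
                cursor += 1
                wells.append((r, c, "sample", g, s))
            else:
                wells.append((r, c, "empty", None, None))
        layouts.append(wells)

    batch_offsets = {
        (rep, ch): batch_rng.normal(0.0, cfg.batch_sd)
        for rep in range(1, cfg.n_replicates + 1) for ch in cfg.channels
    }

    records, latent = [], []
    for rep in range(1, cfg.n_replicates + 1):
        for p in range(n_plates):
            rng = np.random.default_rng(plate_children[(rep - 1) * n_plates + p])
            r_art = rng.standard_normal(cfg.n_rows)
            c_art = rng.standard_normal(cfg.n_cols)
            noise = {ch: rng.normal(0.0, cfg.well_sd, size=n_wells) for ch in cfg.channels}
            plate_id = f"P{p + 1:02d}"
            batch_id = f"B{rep}"
            for w, (r, c, role, gene, sirna) in enumerate(layouts[p]):
                spatial = cfg.row_amp * r_art[r] + cfg.col_amp * c_art[c]
                for ch in cfg.channels:
                    if role == "empty":
                        value = math.nan
                        effect = 0.0
                    else:
                        if role == "positive_control":
                            effect = cfg._pos_effect(ch)
                        elif role == "sample" and gene in true_hits[ch]:
                            effect = cfg.effect_size[ch]
                        else:
                            effect = 0.0
                        raw = (cfg.baseline[ch] + spatial + batch_offsets[(rep, ch)]
                               + effect + noise[ch][w])
                        value = float(_truncate(np.array([raw]), ch)[0])
                    records.append((plate_id, batch_id, rep, r, c, role, gene, sirna,
                                    ch, value))
                    latent.append((plate_id, rep, r, c, ch, spatial,
                                   batch_offsets[(rep, ch)], effect,
                                   0.0 if role == "empty" else noise[ch][w]))

    data = pd.DataFrame(records, columns=[
        "plate_id", "batch_id", "replicate", "row", "col", "role", "gene",
        "sirna_id", "channel", "value"])
    data["gene"] = data["gene"].astype("string")
    data["sirna_id"] = data["sirna_id"].astype("string")
    components = pd.DataFrame(latent, columns=[
        "plate_id", "replicate", "row", "col", "channel",
        "spatial", "batch", "effect", "noise"])

    pms = PlateMeasurementSet(data, n_rows=cfg.n_rows, n_cols=cfg.n_cols)
    return pms, GroundTruth(true_hits=true_hits, genes=genes, components=components)


def simulate_coculture(
    n_wells: int,
    killing_effect: float = -50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    *,
    enhancer_fraction: float = 0.5,
    growth_baseline: float = 20.0,
    nk_baseline: float = -10.0,
    count_t0: float = 1000.0,
    effector_ratio: float = 2.0,
) -> tuple[pd.DataFrame, frozenset]:
    """Generate paired NK / no-NK coculture wells with known enhancer wells.

    The no-NK arm changes by ``growth_baseline`` percent on average (net
    growth/arrest of the targets alone); the NK arm by ``nk_baseline``,
    shifted by ``killing_effect`` in the designated enhancer wells.
    Returns one row per (well, arm) with t0/end counts and the percent
    change, plus the set of enhancer well ids.
    """
    rng = np.random.default_rng(seed)
    n_enh = int(round(enhancer_fraction * n_wells))
    enhancers = frozenset(f"W{i + 1:03d}" for i in rng.choice(n_wells, n_enh, replace=False))

    rows = []
    for i in range(n_wells):
        wid = f"W{i + 1:03d}"
        pc_no_nk = rng.normal(growth_baseline, noise_sd)
        pc_nk = rng.normal(nk_baseline, noise_sd) + (killing_effect if wid in enhancers else 0.0)
        for arm, ratio, pc in (("no_nk", 0.0, pc_no_nk), ("nk", effector_ratio, pc_nk)):
            pc = max(pc, -100.0)
            end = count_t0 * (1.0 + pc / 100.0)
            rows.append(dict(well_id=wid, arm=arm, effector_ratio=ratio,
                             count_t0=count_t0, count_end=end, percent_change=pc,
                             is_enhancer=wid in enhancers))
    return pd.DataFrame(rows), enhancers


def evaluate_recovery(called, truth, channel: str | None = None) -> dict[str, float | None]:
    """Confusion-matrix summary of a called hit set against ground truth.

    ``called`` is a set of genes (or a channel -> set mapping combined with
    ``channel``); ``truth`` is a :class:`GroundTruth` or a plain set, with
    the gene universe taken from the former when available.  Ratios with a
    zero denominator are reported as None (undefined), never 0.
    """
    if isinstance(called, dict):
        if channel is None:
            raise ValueError("channel required when called is a per-channel mapping")
        called = called[channel]
    called = set(called)

    if isinstance(truth, GroundTruth):
        universe = set(truth.genes)
        true_set = set(truth.true_hits[channel] if channel else truth.hits_any_channel())
    else:
        true_set = set(truth)
        universe = None

    if universe is not None:
        stray = called - universe
        if stray:
            raise ValueError(f"called genes outside the simulated universe: {sorted(stray)[:5]}")

    tp = len(called & true_set)
    fp = len(called - true_set)
    fn = len(true_set - called)
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    fdr = fp / (tp + fp) if (tp + fp) else None
    return {"sensitivity": sensitivity, "precision": precision, "fdr": fdr,
            "tp": tp, "fp": fp, "fn": fn}
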