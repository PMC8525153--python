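"""Upstream event selection: live / singlet / CD45+ gates and subsampling.

The original acquisition gates (manual, in Cytobank) are replaced by explicit
threshold rules evaluated on the transformed scale, followed by per-sample
fixed-size uniform subsampling (5000 CD45+ events by default) and pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import Cohort, EventMatrix
from .transform import estimate_autolgcl, logicle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PregateConfig:
    """Threshold surrogates for the acquisition gates.

    CD45 positivity mirrors the global >= 1 decade criterion; viability keeps
    events *below* a cisplatin-channel maximum, DNA keeps events *above* an
    intercalator minimum.  ``subsample_n`` events per sample are then drawn
    without replacement, with per-sample seeds derived from the master seed.
    """

    cd45_threshold: float = 1.0
    cd45_marker: str = "CD45"
    viability_rule: tuple[str, float] | None = None   # (channel, max value)
    dna_rule: tuple[str, float] | None = None         # (channel, min value)
    subsample_n: int = 5000
    seed: int = 0
    shortfall_policy: str = "take_all_warn"           # or "error"

    def __post_init__(self) -> None:
        if self.subsample_n <= 0:
            raise ValueError("subsample_n must be > 0")
        if not np.isfinite(self.cd45_threshold):
            raise ValueError("cd45_threshold must be finite")
        if self.shortfall_policy not in ("error", "take_all_warn"):
            raise ValueError(f"bad shortfall_policy {self.shortfall_policy!r}")


def _rule_values(em: EventMatrix, channel: str) -> np.ndarray:
    """Channel values on the transformed scale.

    Pre-gating precedes the cohort-wide merge-and-transform, so for raw
    input the rule channel is viewed through a temporary per-sample
    autoLgcl transform; transformed input is thresholded directly.
    """
    vals = em.data[channel].to_numpy(dtype=float)
    if em.scale_state == "raw":
        return logicle(vals, estimate_autolgcl(vals))
    return vals


def pregate(em: EventMatrix, cfg: PregateConfig) -> EventMatrix:
    """Retain events passing every enabled rule (transformed scale)."""
    mask = np.ones(em.n_events, dtype=bool)
    rules: list[tuple[str, np.ndarray]] = []
    if cfg.cd45_marker not in em.data.columns:
        raise ValueError(f"CD45 rule references missing channel "
                         f"{cfg.cd45_marker!r}")
    rules.append((
        "cd45_pos",
        _rule_values(em, cfg.cd45_marker) >= cfg.cd45_threshold,
    ))
    if cfg.viability_rule is not None:
        ch, vmax = cfg.viability_rule
        if ch not in em.data.columns:
            raise ValueError(f"viability rule references missing channel {ch!r}")
        rules.append(("live", _rule_values(em, ch) < vmax))
    if cfg.dna_rule is not None:
        ch, vmin = cfg.dna_rule
        if ch not in em.data.columns:
            raise ValueError(f"DNA rule references missing channel {ch!r}")
        rules.append(("singlet", _rule_values(em, ch) > vmin))
    for name, rule_mask in rules:
        mask &= rule_mask
        logger.info("pregate %s: %s retains %d/%d",
                    em.sample_id, name, int(mask.sum()), em.n_events)
    return em.take(np.flatnonzero(mask))


def subsample(em: EventMatrix, n: int, seed: int,
              policy: str = "take_all_warn") -> EventMatrix:
    """Uniform sampling of exactly ``n`` events without replacement.

    Deterministic given ``seed``.  Shortfall handling follows ``policy``:
    ``error`` raises; ``take_all_warn`` returns all events with a warning.
    """
    if em.n_events < n:
        if policy == "error":
            raise ValueError(
                f"sample {em.sample_id}: {em.n_events} events < requested {n}"
            )
        logger.warning("sample %s: only %d events available (< %d); taking all",
                       em.sample_id, em.n_events, n)
        return em.take(np.arange(em.n_events))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(em.n_events, size=n, replace=False))
    return em.take(idx)


def pregate_and_subsample(c: Cohort, cfg: PregateConfig
                          ) -> tuple[Cohort, pd.DataFrame]:
    """Per-sample pregate + subsample; returns new cohort and retention report.

    Per-sample seeds are ``cfg.seed + sample index`` so a run is reproducible
    independent of which samples it contains.
    """
    out, rows = [], []
    for i, s in enumerate(c.samples):
        gated = pregate(s, cfg)
        sub = subsample(gated, cfg.subsample_n, cfg.seed + i,
                        cfg.shortfall_policy)
        out.append(sub)
        rows.append((s.sample_id, s.n_events, gated.n_events, sub.n_events))
    report = pd.DataFrame(
        rows, columns=["sample_id", "events_in", "cd45_pos", "subsampled"]
    )
    return Cohort(samples=out, panel=c.panel), report


def pool(c: Cohort) -> EventMatrix:
    """Row-concatenate all samples, tagging each event with its sample/stage."""
    if not c.samples:
        raise ValueError("empty cohort")
    states = {s.scale_state for s in c.samples}
    if len(states) > 1:
        raise ValueError("cannot pool samples with mixed scale states")
    frames, anns = [], []
    for s in c.samples:
        frames.append(s.data)
        ann = s.annotations.copy() if len(s.annotations) else pd.DataFrame(
            index=range(s.n_events))
        ann["sample_id"] = s.sample_id
        ann["stage"] = s.stage
        anns.append(ann)
    data = pd.concat(frames, ignore_index=True)
    annotations = pd.concat(anns, ignore_index=True)
    return EventMatrix(
        data=data, sample_id="__pooled__", stage=None,
        scale_state=states.pop(), annotations=annotations,
    )
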