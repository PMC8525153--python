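"""Hierarchical ILC gating, subset frequencies and cohort summaries.

Every CD45+ event is assigned exactly one label by threshold positivity on
the transformed (logicle-decade) scale — a value is positive iff it is
greater than or equal to the threshold (default 1 decade):

* any lineage marker (CD3, CD19, CD14, ILT3) positive, or CD56 positive, or
  CD127 negative                      -> nonILC
* else CRTH2 positive                 -> ILC2
* else c-Kit positive                 -> ILC3, split by NKp44 into
  ILC3_NKp44pos / ILC3_NKp44neg
* else                                -> ILC1

The CRTH2 branch precedes c-Kit because ILC2 is defined without reference to
c-Kit while ILC3 requires CRTH2 negativity; NKp44 is consulted only inside
the ILC3 branch.  All subset percentages use CD45+ events as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .panel_io import Cohort, EventMatrix


class PhenotypeLabel(str, Enum):
    ILC1 = "ILC1"
    ILC2 = "ILC2"
    ILC3_NKp44pos = "ILC3_NKp44pos"
    ILC3_NKp44neg = "ILC3_NKp44neg"
    nonILC = "nonILC"


ILC_LABELS = (
    PhenotypeLabel.ILC1, PhenotypeLabel.ILC2,
    PhenotypeLabel.ILC3_NKp44pos, PhenotypeLabel.ILC3_NKp44neg,
)


@dataclass(frozen=True)
class GatingConfig:
    """Threshold and marker-name bindings for the hierarchical gate."""

    positivity_threshold: float = 1.0
    lineage_markers: tuple[str, ...] = ("CD3", "CD19", "CD14", "ILT3")
    cd56: str = "CD56"
    cd127: str = "CD127"
    crth2: str = "CRTH2"
    ckit: str = "c-Kit"
    nkp44: str = "NKp44"

    def __post_init__(self) -> None:
        if not np.isfinite(self.positivity_threshold):
            raise ValueError("positivity_threshold must be finite")

    @property
    def required_markers(self) -> tuple[str, ...]:
        return self.lineage_markers + (
            self.cd56, self.cd127, self.crth2, self.ckit, self.nkp44)


def is_positive(value, cfg: GatingConfig | None = None):
    """Positivity on the transformed scale: value >= threshold (inclusive)."""
    threshold = (cfg or GatingConfig()).positivity_threshold
    out = np.asarray(value, dtype=float) >= threshold
    return bool(out) if out.ndim == 0 else out


def classify_event(marker_values: "pd.Series | dict",
                   cfg: GatingConfig | None = None) -> PhenotypeLabel:
    """Label a single (already CD45+) event; see the module docstring."""
    cfg = cfg or GatingConfig()
    mv = dict(marker_values)
    missing = [m for m in cfg.required_markers if m not in mv]
    if missing:
        raise KeyError(f"event lacks gating marker(s): {missing}")
    pos = lambda m: is_positive(mv[m], cfg)  # noqa: E731
    if any(pos(m) for m in cfg.lineage_markers) or pos(cfg.cd56) \
            or not pos(cfg.cd127):
        return PhenotypeLabel.nonILC
    if pos(cfg.crth2):
        return PhenotypeLabel.ILC2
    if pos(cfg.ckit):
        return (PhenotypeLabel.ILC3_NKp44pos if pos(cfg.nkp44)
                else PhenotypeLabel.ILC3_NKp44neg)
    return PhenotypeLabel.ILC1


def classify_events(em: EventMatrix,
                    cfg: GatingConfig | None = None) -> EventMatrix:
    """Vectorized gate over all events; appends a ``phenotype`` annotation."""
    cfg = cfg or GatingConfig()
    missing = [m for m in cfg.required_markers if m not in em.data.columns]
    if missing:
        raise KeyError(f"events lack gating marker(s): {missing}")
    if em.scale_state != "transformed":
        raise ValueError("gating requires transformed-scale events")
    t = cfg.positivity_threshold
    d = em.data
    lin_pos = np.zeros(em.n_events, dtype=bool)
    for m in cfg.lineage_markers:
        lin_pos |= d[m].to_numpy() >= t
    cd56 = d[cfg.cd56].to_numpy() >= t
    cd127 = d[cfg.cd127].to_numpy() >= t
    crth2 = d[cfg.crth2].to_numpy() >= t
    ckit = d[cfg.ckit].to_numpy() >= t
    nkp44 = d[cfg.nkp44].to_numpy() >= t

    labels = np.full(em.n_events, PhenotypeLabel.nonILC.value, dtype=object)
    ilc = ~lin_pos & ~cd56 & cd127
    labels[ilc & crth2] = PhenotypeLabel.ILC2.value
    ilc3 = ilc & ~crth2 & ckit
    labels[ilc3 & nkp44] = PhenotypeLabel.ILC3_NKp44pos.value
    labels[ilc3 & ~nkp44] = PhenotypeLabel.ILC3_NKp44neg.value
    labels[ilc & ~crth2 & ~ckit] = PhenotypeLabel.ILC1.value

    ann = em.annotations.copy() if len(em.annotations) else pd.DataFrame(
        index=range(em.n_events))
    ann["phenotype"] = labels
    out = EventMatrix(
        data=em.data, sample_id=em.sample_id, stage=em.stage,
        scale_state=em.scale_state, annotations=ann,
    )
    return out


_PCT_COLS = {
    PhenotypeLabel.ILC1: "pct_ILC1",
    PhenotypeLabel.ILC2: "pct_ILC2",
    PhenotypeLabel.ILC3_NKp44pos: "pct_ILC3_NKp44pos",
    PhenotypeLabel.ILC3_NKp44neg: "pct_ILC3_NKp44neg",
}


def _freq_row(labels: np.ndarray, sample_id: str, stage) -> dict:
    n = len(labels)
    if n == 0:
        raise ValueError(f"sample {sample_id}: zero CD45+ events")
    row: dict = {"sample_id": sample_id, "stage": stage, "n_cd45": n}
    n_ilc = 0
    for lab, col in _PCT_COLS.items():
        count = int((labels == lab.value).sum())
        row[col] = 100.0 * count / n
        n_ilc += count
    row["n_ilc_total"] = n_ilc
    return row


def compute_frequencies(c: Cohort) -> pd.DataFrame:
    """Per-sample ILC subset percentages of CD45+ events, plus a pooled row.

    Requires every sample to carry a ``phenotype`` annotation from
    :func:`classify_events`.
    """
    rows = []
    all_labels = []
    for s in c.samples:
        if "phenotype" not in s.annotations.columns:
            raise ValueError(f"sample {s.sample_id} is not classified")
        labels = s.annotations["phenotype"].to_numpy()
        rows.append(_freq_row(labels, s.sample_id, s.stage))
        all_labels.append(labels)
    pooled = np.concatenate(all_labels)
    rows.append(_freq_row(pooled, "__pooled__", None))
    return pd.DataFrame(rows)


def frequencies_from_pooled(pooled: EventMatrix) -> pd.DataFrame:
    """Like :func:`compute_frequencies`, from a pooled event matrix whose
    annotations carry ``phenotype``, ``sample_id`` and ``stage`` columns."""
    ann = pooled.annotations
    for col in ("phenotype", "sample_id"):
        if col not in ann.columns:
            raise ValueError(f"pooled events lack {col!r} annotation")
    rows = []
    for sid, grp in ann.groupby("sample_id", sort=False):
        stage = grp["stage"].iloc[0] if "stage" in grp.columns else None
        rows.append(_freq_row(grp["phenotype"].to_numpy(), str(sid), stage))
    rows.append(_freq_row(ann["phenotype"].to_numpy(), "__pooled__", None))
    return pd.DataFrame(rows)


def coexpression_fraction(em: EventMatrix, marker_a: str, marker_b: str,
                          cfg: GatingConfig | None = None) -> float:
    """Fraction of events positive for both markers (symmetric in order)."""
    cfg = cfg or GatingConfig()
    for m in (marker_a, marker_b):
        if m not in em.data.columns:
            raise KeyError(f"marker {m!r} not in events")
    if em.n_events == 0:
        raise ValueError("empty event selection")
    t = cfg.positivity_threshold
    both = ((em.data[marker_a].to_numpy() >= t)
            & (em.data[marker_b].to_numpy() >= t))
    return float(both.mean())


def summarize_cohort(metadata: pd.DataFrame,
                     columns: list[str] | None = None) -> pd.DataFrame:
    """Per-category counts and percentages of a clinical table.

    Percentages are of the full cohort (100 * count / N), rounded to two
    decimals, one output row per (variable, category).
    """
    if metadata is None or len(metadata) == 0:
        raise ValueError("empty clinical metadata")
    cols = columns or [c for c in metadata.columns if c != "sample_id"]
    n = len(metadata)
    rows = []
    for col in cols:
        counts = metadata[col].value_counts(dropna=False)
        for cat, count in counts.items():
            rows.append({
                "variable": col, "category": cat, "count": int(count),
                "percent": round(100.0 * count / n, 2),
            })
    return pd.DataFrame(rows)
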