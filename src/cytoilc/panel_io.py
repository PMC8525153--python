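"""Panel configuration and cytometry event I/O.

The canonical in-memory containers are :class:`PanelConfig` (marker/channel map
plus the named marker sets used by the gate), :class:`EventMatrix` (one
sample's events-by-markers table with metadata and per-event annotations) and
:class:`Cohort` (an ordered list of samples sharing one panel).

CSV with a marker-name header is the primary interchange format; FCS 3.1 is
supported for realism (see :mod:`cytoilc._fcs`).  Marker names are matched
case-insensitively and metal-isotope prefixes such as ``156Gd_`` in FCS $PnS
fields are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_METAL_RE = re.compile(r"^\d{2,3}[A-Za-z]{1,2}_")


def canonical_marker(name: str) -> str:
    """Normalize a channel/marker name: strip metal tags, lowercase."""
    return _METAL_RE.sub("", str(name).strip()).lower()


# The 36 antibody targets of the staining panel: 27 surface + 9 intracellular.
_SURFACE = [
    "CD45", "PD-1", "Tim3", "CD94", "CD56", "TIGIT", "CD103", "NKG2D",
    "CD127", "ILT3", "CCR6", "CRTH2", "NKp46", "CD161", "NKp30", "CD69",
    "CD38", "CD57", "CD226", "CD16", "c-Kit", "CD14", "CD19", "CD8a",
    "CD3", "NKp44", "CD4",
]
_INTRACELLULAR = [
    "RORgt", "Eomes", "IFN-g", "IL-13", "IL-22", "IL-17A", "perforin",
    "GATA-3", "Tbet",
]

LINEAGE_MARKERS = ("CD3", "CD19", "CD14", "ILT3")
IDENTIFICATION_MARKERS = ("CD45", "CD56", "CD127", "CRTH2", "c-Kit", "NKp44")

#: Required for the hierarchical ILC gate; absence is a hard error.
_REQUIRED_ID = ("CD45", "CD56", "CD127", "CRTH2", "c-Kit", "NKp44")


@dataclass(frozen=True)
class PanelConfig:
    """Marker panel: channel map plus the named marker sets.

    Parameters
    ----------
    markers
        Ordered ``(marker_name, channel_id)`` pairs; order is canonical for
        every :class:`EventMatrix` column layout.
    lineage_markers, identification_markers, functional_markers
        Pairwise-disjoint marker-name sets.  Lineage positivity excludes an
        event from the ILC gate; identification markers drive the gate
        hierarchy; the rest are functional/regulatory read-outs.
    """

    markers: tuple[tuple[str, str], ...]
    lineage_markers: frozenset[str]
    identification_markers: frozenset[str]
    functional_markers: frozenset[str]
    viability_channel: str | None = None
    dna_channel: str | None = None

    def __post_init__(self) -> None:
        names = [m for m, _ in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names in panel: {dupes}")
        name_set = set(names)
        for label, group in (
            ("lineage", self.lineage_markers),
            ("identification", self.identification_markers),
            ("functional", self.functional_markers),
        ):
            missing = set(group) - name_set
            if missing:
                raise ValueError(
                    f"{label} markers not in panel: {sorted(missing)}"
                )
        sets = [self.lineage_markers, self.identification_markers,
                self.functional_markers]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"marker sets overlap: {sorted(overlap)}"
                    )
        missing_id = [m for m in _REQUIRED_ID if m not in name_set]
        if missing_id:
            raise ValueError(
                "panel lacks identification markers required for ILC gating: "
                f"{missing_id}"
            )

    @property
    def marker_names(self) -> list[str]:
        return [m for m, _ in self.markers]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def resolve(self, name: str) -> str:
        """Map an external channel/marker name onto a panel marker name."""
        canon = canonical_marker(name)
        for m, ch in self.markers:
            if canonical_marker(m) == canon or canonical_marker(ch) == canon:
                return m
        raise KeyError(name)


def default_panel() -> PanelConfig:
    """The shipped 36-target bladder-tumor ILC panel.

    Channel ids are synthetic metal-tagged names (the study's clone/metal
    table applies only to its own acquisition); analysis joins on marker name.
    """
    all_markers = _SURFACE + _INTRACELLULAR
    metals = [f"{140 + i}Nd_" for i in range(len(all_markers))]
    markers = tuple(
        (m, f"{metal}{m}") for m, metal in zip(all_markers, metals)
    )
    lineage = frozenset(LINEAGE_MARKERS)
    ident = frozenset(IDENTIFICATION_MARKERS)
    functional = frozenset(all_markers) - lineage - ident
    return PanelConfig(
        markers=markers,
        lineage_markers=lineage,
        identification_markers=ident,
        functional_markers=functional,
    )


def load_panel(path: str | Path) -> PanelConfig:
    """Read a YAML/JSON panel config and validate it.

    The file declares ``markers`` (list of names, or name->channel mapping)
    and the named sets ``lineage_markers``, ``identification_markers``,
    ``functional_markers``; unnamed markers default into the functional set.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "markers" not in raw:
        raise ValueError(f"panel config {path} must declare 'markers'")
    m = raw["markers"]
    if isinstance(m, dict):
        markers = tuple((str(k), str(v)) for k, v in m.items())
    else:
        markers = tuple(
            (str(x), str(x)) if isinstance(x, str)
            else (str(x[0]), str(x[1])) for x in m
        )
    names = {mm for mm, _ in markers}
    lineage = frozenset(raw.get("lineage_markers", LINEAGE_MARKERS) or ())
    ident = frozenset(
        raw.get("identification_markers", IDENTIFICATION_MARKERS) or ()
    )
    functional = frozenset(
        raw.get("functional_markers", sorted(names - lineage - ident))
    )
    return PanelConfig(
        markers=markers,
        lineage_markers=lineage,
        identification_markers=ident,
        functional_markers=functional,
        viability_channel=raw.get("viability_channel"),
        dna_channel=raw.get("dna_channel"),
    )


@dataclass
class EventMatrix:
    """One sample's events-by-markers intensity table.

    ``scale_state`` is ``'raw'`` (non-negative dual counts) or
    ``'transformed'`` (logicle decades).  ``annotations`` is an index-aligned
    per-event table (phenotype label, cluster id, ...); row operations keep it
    aligned.
    """

    data: pd.DataFrame
    sample_id: str
    stage: str | None = None
    scale_state: str = "raw"
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.scale_state not in ("raw", "transformed"):
            raise ValueError(f"bad scale_state {self.scale_state!r}")
        if self.scale_state == "raw" and len(self.data):
            if (self.data.to_numpy() < 0).any():
                raise ValueError(
                    f"sample {self.sample_id}: raw-scale values must be >= 0"
                )
        if len(self.annotations) and len(self.annotations) != len(self.data):
            raise ValueError("annotations not aligned with events")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def take(self, indices: np.ndarray | Sequence[int]) -> "EventMatrix":
        """Row selection that keeps annotations aligned."""
        idx = np.asarray(indices)
        ann = (
            self.annotations.iloc[idx].reset_index(drop=True)
            if len(self.annotations) else pd.DataFrame()
        )
        return EventMatrix(
            data=self.data.iloc[idx].reset_index(drop=True),
            sample_id=self.sample_id,
            stage=self.stage,
            scale_state=self.scale_state,
            annotations=ann,
        )

    def with_values(self, values: np.ndarray, scale_state: str
                    ) -> "EventMatrix":
        df = pd.DataFrame(values, columns=self.data.columns)
        return replace(self, data=df, scale_state=scale_state)


@dataclass
class Cohort:
    """Ordered samples sharing one panel; sample ids unique."""

    samples: list[EventMatrix]
    panel: PanelConfig

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in cohort")
        for s in self.samples:
            if list(s.data.columns) != self.panel.marker_names:
                raise ValueError(
                    f"sample {s.sample_id} columns do not match panel"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def _canonicalize_columns(df: pd.DataFrame, panel: PanelConfig,
                          source: str) -> pd.DataFrame:
    """Reorder/rename columns to panel order; drop unknowns with a warning."""
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for col in df.columns:
        try:
            mapping[col] = panel.resolve(col)
        except KeyError:
            unknown.append(col)
    if unknown:
        logger.warning("%s: dropping %d unknown channel(s): %s",
                       source, len(unknown), unknown)
    df = df[[c for c in df.columns if c in mapping]].rename(columns=mapping)
    missing = [m for m in _REQUIRED_ID if m not in df.columns]
    if missing:
        raise ValueError(
            f"{source}: missing required identification channel(s) {missing}"
        )
    absent = [m for m in panel.marker_names if m not in df.columns]
    if absent:
        raise ValueError(f"{source}: panel channels absent from file: {absent}")
    return df[panel.marker_names]


def read_events(path: str | Path, panel: PanelConfig,
                sample_id: str | None = None) -> EventMatrix:
    """Read an FCS 3.0/3.1 or CSV event file into panel column order.

    CSV must carry a header row of channel or marker names.  Returns a
    raw-scale :class:`EventMatrix`; ``sample_id`` defaults to the file stem
    (a CSV sidecar ``<stem>.meta.yaml``, if present, overrides it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stage = None
    sid = sample_id
    if path.suffix.lower() == ".fcs":
        from ._fcs import read_fcs
        values, names, text = read_fcs(path)
        df = pd.DataFrame(values, columns=names)
        sid = sid or text.get("$SRC") or path.stem
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"unreadable event file {path}: {exc}") from exc
        meta_path = path.with_suffix(".meta.yaml")
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text()) or {}
            sid = sid or meta.get("sample_id")
            stage = meta.get("stage")
        sid = sid or path.stem
    df = _canonicalize_columns(df, panel, str(path))
    return EventMatrix(
        data=df.astype(float), sample_id=str(sid), stage=stage,
        scale_state="raw",
    )


def write_events(em: EventMatrix, path: str | Path,
                 fcs: bool = False) -> None:
    """Write an :class:`EventMatrix` to CSV (always), plus FCS if requested.

    A ``<stem>.meta.yaml`` sidecar carries sample_id / stage / scale_state so
    a round trip through :func:`read_events` is metadata-preserving.
    """
    if em.n_events == 0:
        raise ValueError("refusing to write an empty EventMatrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path if path.suffix.lower() == ".csv" else path.with_suffix(".csv")
    em.data.to_csv(csv_path, index=False)
    meta = {"sample_id": em.sample_id, "stage": em.stage,
            "scale_state": em.scale_state}
    csv_path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))
    if fcs or path.suffix.lower() == ".fcs":
        from ._fcs import write_fcs
        write_fcs(path.with_suffix(".fcs"), em.data.to_numpy(dtype=np.float32),
                  list(em.data.columns), src=em.sample_id)
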