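"""Seeded generator of CyTOF-like cohorts with known ground truth.

Emulates the statistical structure the pipeline assumes: 21 tumor samples of
CD45+ events; rare ILC subsets at the study frequencies (ILC1 0.78%, ILC2
0.54%, NKp44+ILC3 0.1%, NKp44-ILC3 0.09% of CD45+ cells); abundant T / B /
myeloid / NK filler populations exercising every exclusion branch of the
gate; nine phenotype templates giving the ILC pool a nine-cluster structure;
and a tumor-stage covariate with elevated ILC1 frequency in >=T3 samples.

Raw-scale signal model per marker: positive markers draw from a lognormal
(median 500 counts, sdlog 0.5); negative markers from a zero-inflated
exponential (90% exact zeros, scale 0.3), mimicking CyTOF dual-count output
(exact zeros, right-skewed positives) while keeping positive and negative
populations on opposite sides of the 1-decade threshold after the automatic
logicle transform.

The stage effect is parameterized as the >=T3 : T2 frequency *ratio* with
the cohort-level ILC1 mean pinned at the configured frequency, so pooled
recovery targets and the stage association hold simultaneously.  All
randomness flows from the single spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import Cohort, EventMatrix, PanelConfig, default_panel
from .transform import LogicleParams, biexponential

# reference channel scale used for the template calibration check
_CAL_PARAMS = dict(T=5000.0, M=4.5, W=0.25, A=0.0)


@dataclass(frozen=True)
class PhenotypeTemplate:
    """Raw-scale expression template for one population.

    ``positive_markers`` draw lognormal(signal_meanlog, signal_sdlog);
    ``negative_markers`` (implicitly, every other panel marker) draw a
    zero-inflated exponential.  On construction the template must be
    *calibrated*: under a reference logicle scale, positive markers exceed
    the 1-decade threshold and negative markers stay below it, each with
    probability >= 0.95.
    """

    name: str
    positive_markers: frozenset[str]
    negative_markers: frozenset[str] = frozenset()
    signal_meanlog: float = math.log(500.0)
    signal_sdlog: float = 0.5
    background_zero_fraction: float = 0.9
    background_rate: float = 0.3     # exponential scale (mean), raw counts

    def __post_init__(self) -> None:
        overlap = self.positive_markers & self.negative_markers
        if overlap:
            raise ValueError(f"markers both + and -: {sorted(overlap)}")
        if not (0.0 <= self.background_zero_fraction < 1.0):
            raise ValueError("background_zero_fraction must be in [0, 1)")
        p_pos, p_neg = self.calibration()
        if p_pos < 0.95 or p_neg < 0.95:
            raise ValueError(
                f"template {self.name!r} is uncalibrated: "
                f"P(pos >= 1) = {p_pos:.3f}, P(neg < 1) = {p_neg:.3f}")

    def calibration(self) -> tuple[float, float]:
        """Closed-form threshold separation under the reference scale."""
        from scipy.stats import norm
        x_thr = float(biexponential(1.0, LogicleParams(**_CAL_PARAMS)))
        p_pos = float(norm.sf(
            (math.log(x_thr) - self.signal_meanlog) / self.signal_sdlog))
        zf = self.background_zero_fraction
        p_neg = zf + (1 - zf) * (1 - math.exp(-x_thr / self.background_rate))
        return p_pos, p_neg


# -- nine-cluster ILC template library --------------------------------------
# Each cluster fixes the non-defining embedding markers (CD161, NKp46, NKp30,
# CD69, CCR6), the functional read-outs, and a subtype mix; the defining
# markers (CRTH2, c-Kit, NKp44) follow each event's drawn subtype.  Subtype
# placement follows the observed composition: ILC1 in all nine clusters,
# ILC2 in 2/4/8/9, NKp44+ILC3 in 5, NKp44-ILC3 in 7/8; Th17 program
# (RORgt/IL-17A/IL-22) in clusters 1/3/4/5, Th1 program
# (Tbet/IFN-g/perforin) in 2/8, exhaustion (PD-1/Tim3/TIGIT) in 7/9.

_CLUSTER_SPECS: list[dict] = [
    dict(cluster=1, surface=["CD161", "CCR6"],
         functional=["RORgt", "IL-17A", "IL-22"],
         mix={"ILC1": 0.14}),
    dict(cluster=2, surface=["NKp46", "NKp30", "CD69", "CD38"],
         functional=["Tbet", "IFN-g", "perforin", "GATA-3", "IL-13"],
         mix={"ILC1": 0.06, "ILC2": 0.40}),
    dict(cluster=3, surface=["CD161", "CD69", "CCR6"],
         functional=["RORgt", "IL-17A", "IL-22"],
         mix={"ILC1": 0.16}),
    dict(cluster=4, surface=["NKp46", "NKp30", "CD69", "CCR6", "CD38"],
         functional=["RORgt", "IL-17A", "IL-22", "GATA-3", "IL-13"],
         mix={"ILC1": 0.10, "ILC2": 0.25}),
    dict(cluster=5, surface=["CD161", "NKp46", "CD69", "CCR6", "CD103"],
         functional=["RORgt", "IL-17A", "IL-22"],
         mix={"ILC1": 0.12, "ILC3_NKp44pos": 1.0}),
    dict(cluster=6, surface=[],
         functional=[],
         mix={"ILC1": 0.16}),
    dict(cluster=7, surface=["CD161", "NKp30"],
         functional=["PD-1", "Tim3", "TIGIT"],
         mix={"ILC1": 0.10, "ILC3_NKp44neg": 0.6}),
    dict(cluster=8, surface=["CD161", "NKp46", "NKp30", "CD69", "CCR6",
                             "CD103"],
         functional=["Tbet", "IFN-g", "perforin", "GATA-3", "IL-13"],
         mix={"ILC1": 0.06, "ILC2": 0.20, "ILC3_NKp44neg": 0.4}),
    dict(cluster=9, surface=["NKp30", "CD69"],
         functional=["PD-1", "Tim3", "TIGIT", "GATA-3", "IL-13"],
         mix={"ILC1": 0.10, "ILC2": 0.15}),
]

_SUBTYPE_DEFINING = {
    "ILC1": (),
    "ILC2": ("CRTH2",),
    "ILC3_NKp44pos": ("c-Kit", "NKp44"),
    "ILC3_NKp44neg": ("c-Kit",),
}

_BACKGROUND_SPECS = {
    "T_cell": dict(markers=["CD3", "CD4", "CD8a", "CD127", "CD69",
                            "NKG2D", "CD226"], weight=0.60),
    "NK_cell": dict(markers=["CD56", "CD94", "CD16", "CD57", "NKp46",
                             "NKp30", "NKG2D", "CD226", "Eomes", "Tbet",
                             "perforin", "IFN-g"], weight=0.20),
    "myeloid": dict(markers=["CD14", "ILT3", "CD38"], weight=0.12),
    "B_cell": dict(markers=["CD19"], weight=0.08),
}


def figure3_templates(panel: PanelConfig | None = None
                      ) -> list[PhenotypeTemplate]:
    """The default nine-cluster ILC template library.

    One template per cluster; the returned templates describe the markers
    shared by all subtypes placed in that cluster (CD45 and CD127 positive
    everywhere, defining markers appended per subtype at draw time).
    """
    panel = panel or default_panel()
    out = []
    for spec in _CLUSTER_SPECS:
        pos = frozenset(["CD45", "CD127"] + spec["surface"]
                        + spec["functional"])
        unknown = pos - set(panel.marker_names)
        if unknown:
            raise ValueError(f"template markers not in panel: "
                             f"{sorted(unknown)}")
        out.append(PhenotypeTemplate(
            name=f"cluster{spec['cluster']}", positive_markers=pos))
    return out


def _cluster_allocation() -> dict[str, np.ndarray]:
    """Normalized P(cluster | subtype) over the nine clusters."""
    alloc: dict[str, np.ndarray] = {}
    for subtype in _SUBTYPE_DEFINING:
        w = np.array([spec["mix"].get(subtype, 0.0)
                      for spec in _CLUSTER_SPECS], dtype=float)
        alloc[subtype] = w / w.sum()
    return alloc


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration: the cohort the pipeline is exercised on."""

    n_samples: int = 21
    events_per_sample: int = 6000
    subset_frequencies: tuple[tuple[str, float], ...] = (
        ("ILC1", 0.0078), ("ILC2", 0.0054),
        ("ILC3_NKp44pos", 0.0010), ("ILC3_NKp44neg", 0.0009),
    )
    n_t3plus: int = 9            # of n_samples; first 12 are T2, then 6 T3, 3 T4
    ilc1_enrichment: float = 2.4  # >=T3 : T2 ILC1 frequency ratio
    between_sample_concentration: float | None = None  # beta dispersion, off
    signal_meanlog: float = math.log(500.0)
    signal_sdlog: float = 0.5
    background_zero_fraction: float = 0.9
    background_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.subset_frequencies)
        if any(f < 0 for f in freqs.values()) or sum(freqs.values()) >= 1:
            raise ValueError("subset frequencies must be >= 0 and sum < 1")
        if not (0 <= self.n_t3plus <= self.n_samples):
            raise ValueError("n_t3plus out of range")
        if self.ilc1_enrichment <= 0:
            raise ValueError("ilc1_enrichment must be positive")

    def stage_of(self, sample_index: int) -> str:
        """Deterministic stage assignment: T2 block, then T3, then T4."""
        n_t2 = self.n_samples - self.n_t3plus
        if sample_index < n_t2:
            return "T2"
        n_t3 = int(round(self.n_t3plus * 2 / 3))
        return "T3" if sample_index < n_t2 + n_t3 else "T4"

    def ilc1_frequency(self, stage: str) -> float:
        """Stage-conditional ILC1 frequency with the cohort mean pinned.

        f_T2 solves n_T2 f_T2 + n_T3+ (e f_T2) = n f, so the expected pooled
        ILC1 frequency equals the configured value for any enrichment e.
        """
        f = dict(self.subset_frequencies)["ILC1"]
        n_t2 = self.n_samples - self.n_t3plus
        f_t2 = f * self.n_samples / (n_t2 + self.ilc1_enrichment
                                     * self.n_t3plus)
        return f_t2 if stage == "T2" else self.ilc1_enrichment * f_t2


def _category_probs(spec: SyntheticSpec, stage: str
                    ) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Event categories (population, cluster) and their probabilities."""
    freqs = dict(spec.subset_frequencies)
    freqs["ILC1"] = spec.ilc1_frequency(stage)
    alloc = _cluster_allocation()
    cats: list[tuple[str, int]] = []
    probs: list[float] = []
    for subtype, f in freqs.items():
        for ci, w in enumerate(alloc[subtype]):
            if w > 0:
                cats.append((subtype, ci + 1))
                probs.append(f * w)
    remaining = 1.0 - sum(probs)
    total_bg = sum(s["weight"] for s in _BACKGROUND_SPECS.values())
    for name, s in _BACKGROUND_SPECS.items():
        cats.append((name, 0))
        probs.append(remaining * s["weight"] / total_bg)
    return cats, np.asarray(probs)


def _positive_sets(spec: SyntheticSpec, panel: PanelConfig
                   ) -> dict[tuple[str, int], frozenset[str]]:
    """Positive-marker set per (population, cluster) category."""
    templates = {t.name: t for t in figure3_templates(panel)}
    out: dict[tuple[str, int], frozenset[str]] = {}
    for cspec in _CLUSTER_SPECS:
        ci = cspec["cluster"]
        base = templates[f"cluster{ci}"].positive_markers
        for subtype in cspec["mix"]:
            out[(subtype, ci)] = base | frozenset(
                _SUBTYPE_DEFINING[subtype])
    for name, s in _BACKGROUND_SPECS.items():
        out[(name, 0)] = frozenset(["CD45"] + s["markers"])
    return out


def _draw_matrix(rng: np.random.Generator, n: int, panel: PanelConfig,
                 positive: frozenset[str], spec: SyntheticSpec) -> np.ndarray:
    markers = panel.marker_names
    out = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        if m in positive:
            out[:, j] = rng.lognormal(spec.signal_meanlog,
                                      spec.signal_sdlog, size=n)
        else:
            vals = rng.exponential(spec.background_rate, size=n)
            vals[rng.random(n) < spec.background_zero_fraction] = 0.0
            out[:, j] = vals
    return out


def generate_sample(spec: SyntheticSpec, sample_index: int,
                    panel: PanelConfig | None = None
                    ) -> tuple[EventMatrix, pd.DataFrame]:
    """One sample of raw-scale CD45+ events plus its ground-truth table.

    Deterministic given ``(spec.seed, sample_index)``.  The truth table
    (columns ``population``, ``cluster``) is row-aligned with the events and
    is returned separately — it never travels with the pipeline-visible data.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng([spec.seed, sample_index])
    stage = spec.stage_of(sample_index)
    cats, probs = _category_probs(spec, stage)
    if spec.between_sample_concentration is not None:
        c = spec.between_sample_concentration
        jitter = rng.gamma(np.maximum(c * probs, 1e-9))
        probs = jitter / jitter.sum()
    counts = rng.multinomial(spec.events_per_sample, probs)
    pos_sets = _positive_sets(spec, panel)

    blocks, truth_rows = [], []
    for (cat, count) in zip(cats, counts):
        if count == 0:
            continue
        blocks.append(_draw_matrix(rng, count, panel, pos_sets[cat], spec))
        truth_rows.extend([cat] * count)
    values = np.vstack(blocks)
    truth = pd.DataFrame(truth_rows, columns=["population", "cluster"])
    perm = rng.permutation(len(values))
    values = values[perm]
    truth = truth.iloc[perm].reset_index(drop=True)

    em = EventMatrix(
        data=pd.DataFrame(values, columns=panel.marker_names),
        sample_id=f"S{sample_index + 1:02d}", stage=stage,
        scale_state="raw",
    )
    truth.insert(0, "sample_id", em.sample_id)
    return em, truth


def generate_cohort(spec: SyntheticSpec, panel: PanelConfig | None = None
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Full synthetic cohort and the concatenated ground-truth table."""
    panel = panel or default_panel()
    samples, truths = [], []
    for i in range(spec.n_samples):
        em, truth = generate_sample(spec, i, panel)
        samples.append(em)
        truths.append(truth)
    cohort = Cohort(samples=samples, panel=panel)
    truth = pd.concat(truths, ignore_index=True)
    return cohort, truth
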