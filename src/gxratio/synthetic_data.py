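"""Seeded synthetic qPCR cohorts with planted case/control structure.

Emulates a 47-probe low-density qPCR array (44 targets plus housekeeping
probes, with duplicate probes GNB5-1/-2 and TP53-1/-2) measured on cohorts of
subjects labelled CTRL / IBS / CD / UC / CeD.  Disease effects are planted as
multiplicative fold changes on relative expression, carried by each case
subject independently with a given penetrance — so different case subjects
can owe their signal to different genes, which is exactly the heterogeneity
the downstream ratio search exploits.

The noise model is Gaussian on the CT (log2) scale: replicate qPCR noise is
approximately log-normal in expression space.  An "up" effect of fold f
lowers the probe's CT by log2(f); a "down" effect raises it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np

from .expression_io import CTTable, GROUP_LABELS, CT_CEILING

#: The 47 probes of the emulated low-density array (GAPDH is the normaliser).
PROBE_PANEL = (
    "ABR", "ACTB", "ACTR1A", "ADAMTSL4", "ANAPC1", "APOBEC3F", "ASL", "B2M",
    "BRCA1", "CD55", "CDH1", "CDKN1B", "CHEK2", "CSF3R", "CTSS", "EPHX2",
    "EXT2", "FOS", "FOSL1", "GAPDH", "GATA3", "GNB5-1", "GNB5-2", "GSTM4",
    "HLA-DRA", "HRAS", "IFI27", "IL11RA", "JUN", "KRAS", "LEPREL4", "LLGL2",
    "NRAS", "OAS1", "ORC1L", "PGK1", "PMAIP1", "POU6F1", "RANGAP1", "SC65",
    "SPIB", "TAF11", "TBP", "TGFBR2", "TP53-1", "TP53-2", "TXK",
)

#: Duplicate probes interrogating the same underlying transcript.
DUPLICATE_PROBE_GENE = {
    "GNB5-1": "GNB5", "GNB5-2": "GNB5",
    "TP53-1": "TP53", "TP53-2": "TP53",
}

DEFAULT_REFERENCE_PROBE = "GAPDH"
DEFAULT_CT_NOISE_SD = 0.35
DEFAULT_REFERENCE_CT_MEAN = 20.0


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """One planted disease effect: a fold change on a probe's expression.

    ``penetrance`` is the probability that a given case subject carries the
    effect; carriage is drawn independently per subject and per effect.
    """

    probe_id: str
    direction: str  # "up" or "down"
    fold_change: float
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not self.fold_change > 1:
            raise ValueError(f"fold_change must be > 1, got {self.fold_change}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must lie in [0, 1], got {self.penetrance}")

    @property
    def ct_shift(self) -> float:
        """Shift applied to the probe's CT when the effect is carried."""
        delta = float(np.log2(self.fold_change))
        return -delta if self.direction == "up" else delta


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    group_label: str
    n_subjects: int
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group_label!r}; allowed: {list(GROUP_LABELS)}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "effects", tuple(self.effects))
        probes = [e.probe_id for e in self.effects]
        if len(set(probes)) != len(probes):
            raise ValueError(f"duplicate effect probes in cohort {self.group_label}: {probes}")


def default_baseline_ct_means(panel: Sequence[str] = PROBE_PANEL) -> dict[str, float]:
    """Deterministic per-probe baseline CT means spread over [22, 31] cycles."""
    return {p: 22.0 + (i * 7919) % 91 / 10.0 for i, p in enumerate(panel)}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    cohorts: tuple[CohortSpec, ...]
    seed: int
    panel: tuple[str, ...] = PROBE_PANEL
    reference_probe: str = DEFAULT_REFERENCE_PROBE
    baseline_ct_mean: Mapping[str, float] | None = None
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD
    reference_ct_mean: float = DEFAULT_REFERENCE_CT_MEAN

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required; refusing silent nondeterminism")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.reference_probe not in self.panel:
            raise ValueError(f"reference probe {self.reference_probe!r} not in panel")
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        object.__setattr__(self, "panel", tuple(self.panel))
        baselines = dict(self.baseline_ct_mean) if self.baseline_ct_mean else \
            default_baseline_ct_means(self.panel)
        for probe in self.panel:
            if probe not in baselines:
                raise ValueError(f"no baseline CT mean for probe {probe!r}")
            if not 0 < baselines[probe] <= CT_CEILING:
                raise ValueError(
                    f"baseline CT mean for {probe!r} must lie in (0, {CT_CEILING}]"
                )
        if not 0 < self.reference_ct_mean <= CT_CEILING:
            raise ValueError(f"reference CT mean must lie in (0, {CT_CEILING}]")
        object.__setattr__(self, "baseline_ct_mean", baselines)
        for cohort in self.cohorts:
            for effect in cohort.effects:
                if effect.probe_id not in self.panel:
                    raise ValueError(
                        f"effect probe {effect.probe_id!r} (cohort {cohort.group_label}) "
                        f"is not on the panel"
                    )

    def to_json(self) -> str:
        payload = {
            "panel": list(self.panel),
            "reference_probe": self.reference_probe,
            "baseline_ct_mean": dict(self.baseline_ct_mean),
            "ct_noise_sd": self.ct_noise_sd,
            "reference_ct_mean": self.reference_ct_mean,
            "seed": self.seed,
            "cohorts": [
                {
                    "group_label": c.group_label,
                    "n_subjects": c.n_subjects,
                    "effects": [dataclasses.asdict(e) for e in c.effects],
                }
                for c in self.cohorts
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        payload = json.loads(text)
        cohorts = tuple(
            CohortSpec(
                group_label=c["group_label"],
                n_subjects=c["n_subjects"],
                effects=tuple(EffectSpec(**e) for e in c.get("effects", ())),
            )
            for c in payload["cohorts"]
        )
        return cls(
            cohorts=cohorts,
            seed=payload["seed"],
            panel=tuple(payload.get("panel", PROBE_PANEL)),
            reference_probe=payload.get("reference_probe", DEFAULT_REFERENCE_PROBE),
            baseline_ct_mean=payload.get("baseline_ct_mean"),
            ct_noise_sd=payload.get("ct_noise_sd", DEFAULT_CT_NOISE_SD),
            reference_ct_mean=payload.get("reference_ct_mean", DEFAULT_REFERENCE_CT_MEAN),
        )


def generate_cohorts(config: SyntheticConfig) -> CTTable:
    """Draw a seeded synthetic CT table from a :class:`SyntheticConfig`.

    Per subject and probe: CT = baseline mean + effect shift (if carried) +
    Gaussian noise.  Duplicate probes of one gene share an additional
    per-subject gene-level deviation, so they co-vary as two read-outs of a
    single transcript.  Values above the instrument ceiling are clipped (with
    a warning), mimicking undetected-at-40 behaviour.
    """
    rng = np.random.default_rng(config.seed)
    panel = list(config.panel)
    ref_idx = panel.index(config.reference_probe)
    base = np.array([config.baseline_ct_mean[p] for p in panel])
    base[ref_idx] = config.reference_ct_mean

    dup_genes = sorted({g for p, g in DUPLICATE_PROBE_GENE.items() if p in panel})
    subject_ids: list[str] = []
    groups: dict[str, str] = {}
    rows: list[np.ndarray] = []
    n_clipped = 0
    for cohort in config.cohorts:
        shifts = {panel.index(e.probe_id): e for e in cohort.effects}
        for k in range(cohort.n_subjects):
            sid = f"{cohort.group_label}_{len(subject_ids):04d}"
            ct = base + rng.normal(0.0, config.ct_noise_sd, size=len(panel))
            # shared transcript-level deviation for duplicate probes
            for gene in dup_genes:
                dev = rng.normal(0.0, config.ct_noise_sd)
                for j, probe in enumerate(panel):
                    if DUPLICATE_PROBE_GENE.get(probe) == gene:
                        ct[j] += dev
            for j, effect in shifts.items():
                if rng.random() < effect.penetrance:
                    ct[j] += effect.ct_shift
            high = ct > CT_CEILING
            n_clipped += int(high.sum())
            ct = np.clip(ct, 1e-2, CT_CEILING)
            subject_ids.append(sid)
            groups[sid] = cohort.group_label
            rows.append(ct)
    if n_clipped:
        warnings.warn(f"{n_clipped} CT values clipped at the {CT_CEILING}-cycle ceiling")
    return CTTable(subject_ids=subject_ids, probe_ids=panel,
                   ct=np.vstack(rows), groups=groups)


#: Planted over/under-expression patterns per disease cohort, mirroring the
#: qualitative structure the analysis expects: PGK1 up everywhere; a block of
#: genes up only in IBS and CeD; a block down only in CD and UC; and a block
#: down only in CD.  Folds span 2-4x, penetrance 0.5 except the ubiquitous
#: PGK1 effect (0.9, so it stays detectable even in the smallest cohort).
FIGURE_PATTERN_EFFECTS: dict[str, tuple[EffectSpec, ...]] = {
    "CD": (
        EffectSpec("PGK1", "up", 4.0, 0.9),
        EffectSpec("APOBEC3F", "down", 3.0, 0.5),
        EffectSpec("ASL", "down", 3.0, 0.5),
        EffectSpec("SPIB", "down", 2.0, 0.5),
        EffectSpec("ANAPC1", "down", 4.0, 0.5),
        EffectSpec("RANGAP1", "down", 3.0, 0.5),
        EffectSpec("TP53-1", "down", 2.0, 0.5),
        EffectSpec("TP53-2", "down", 2.0, 0.5),
    ),
    "UC": (
        EffectSpec("PGK1", "up", 4.0, 0.9),
        EffectSpec("APOBEC3F", "down", 3.0, 0.5),
        EffectSpec("ASL", "down", 3.0, 0.5),
        EffectSpec("SPIB", "down", 2.0, 0.5),
        EffectSpec("GNB5-1", "down", 2.0, 0.5),
        EffectSpec("GNB5-2", "down", 2.0, 0.5),
    ),
    "IBS": (
        EffectSpec("PGK1", "up", 4.0, 0.9),
        EffectSpec("ABR", "up", 3.0, 0.5),
        EffectSpec("ACTR1A", "up", 2.0, 0.5),
        EffectSpec("EXT2", "up", 3.0, 0.5),
        EffectSpec("HRAS", "up", 4.0, 0.5),
        EffectSpec("KRAS", "up", 2.0, 0.5),
    ),
    "CeD": (
        EffectSpec("PGK1", "up", 4.0, 0.9),
        EffectSpec("ABR", "up", 3.0, 0.5),
        EffectSpec("ACTR1A", "up", 2.0, 0.5),
        EffectSpec("EXT2", "up", 3.0, 0.5),
        EffectSpec("HRAS", "up", 4.0, 0.5),
        EffectSpec("KRAS", "up", 2.0, 0.5),
    ),
}

#: Cohort sizes of the emulated study population.
PAPERLIKE_COHORT_SIZES = {"CTRL": 113, "CD": 46, "UC": 40, "IBS": 44, "CeD": 16}


def paperlike_config(seed: int = 0,
                     cohort_sizes: Mapping[str, int] | None = None,
                     ct_noise_sd: float = DEFAULT_CT_NOISE_SD) -> SyntheticConfig:
    """47-probe config with study-sized cohorts and planted disease patterns."""
    sizes = dict(cohort_sizes or PAPERLIKE_COHORT_SIZES)
    cohorts = [CohortSpec("CTRL", sizes.pop("CTRL"))]
    for label, n in sizes.items():
        cohorts.append(CohortSpec(label, n, FIGURE_PATTERN_EFFECTS[label]))
    return SyntheticConfig(cohorts=tuple(cohorts), seed=seed, ct_noise_sd=ct_noise_sd)


def _tiny_table() -> CTTable:
    # Hand-auditable: 6 probes, 8 subjects, exact rational CTs, no RNG.
    # Cases have A two cycles lower (4x up) and B two cycles higher (4x down)
    # than controls, so the ratio A/B separates them perfectly.
    probes = ["GAPDH", "A", "B", "C", "D", "E"]
    subjects = [f"CTRL_{i}" for i in range(4)] + [f"CD_{i}" for i in range(4)]
    groups = {s: ("CTRL" if s.startswith("CTRL") else "CD") for s in subjects}
    ct = np.array([
        # GAPDH   A      B      C      D      E
        [20.0, 24.00, 26.00, 28.00, 22.00, 25.00],
        [20.0, 24.25, 25.75, 27.50, 22.50, 25.25],
        [20.0, 23.75, 26.25, 28.50, 21.50, 24.75],
        [20.0, 24.50, 25.50, 28.25, 22.25, 25.50],
        [20.0, 22.00, 28.00, 28.00, 22.00, 25.00],
        [20.0, 22.25, 27.75, 27.75, 22.25, 25.25],
        [20.0, 21.75, 28.25, 28.25, 21.75, 24.75],
        [20.0, 22.50, 27.50, 28.50, 21.50, 25.50],
    ])
    return CTTable(subject_ids=subjects, probe_ids=probes, ct=ct, groups=groups)


def make_fixture(kind: str, seed: int = 0) -> CTTable:
    """Build a named test cohort: ``tiny`` (hand-auditable) or ``paperlike``."""
    if kind == "tiny":
        return _tiny_table()
    if kind == "paperlike":
        return generate_cohorts(paperlike_config(seed=seed))
    raise ValueError(f"unknown fixture kind {kind!r}; expected 'tiny' or 'paperlike'")
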