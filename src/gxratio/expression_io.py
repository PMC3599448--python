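"""Read/write qPCR threshold-cycle tables and convert them to relative expression.

A CT table holds raw threshold-cycle values (cycles; lower = more transcript)
for a set of subjects and probes, together with a group label per subject.
Relative expression is computed against a reference (housekeeping) probe as
``2**(ct[reference] - ct[target])``, so a target amplifying two cycles earlier
than the reference has relative level 4.0.

On-disk format is plain TSV: one file with subjects as rows and probes as
columns (first column ``subject_id``), and a metadata TSV with columns
``subject_id`` and ``group``.  Missing CT values (undetected wells) are
encoded as an empty field or the literal ``Undetermined``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Group labels accepted in subject metadata.
GROUP_LABELS = ("CTRL", "IBS", "CD", "UC", "CeD")

#: Tokens read as a missing CT value.
MISSING_TOKENS = frozenset({"", "Undetermined", "NA", "NaN", "nan"})

#: Instrument ceiling: CT values are clipped here and treated as "undetected or at limit".
CT_CEILING = 40.0


def _check_ids(subject_ids: Sequence[str], probe_ids: Sequence[str],
               n_rows: int, n_cols: int, groups: Mapping[str, str]) -> None:
    if len(subject_ids) != n_rows or len(probe_ids) != n_cols:
        raise ValueError(
            f"matrix shape ({n_rows}, {n_cols}) does not match "
            f"{len(subject_ids)} subjects x {len(probe_ids)} probes"
        )
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if list(subject_ids).count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    if len(set(probe_ids)) != len(probe_ids):
        dupes = sorted({p for p in probe_ids if list(probe_ids).count(p) > 1})
        raise ValueError(f"duplicate probe ids: {dupes}")
    missing = [s for s in subject_ids if s not in groups]
    if missing:
        raise ValueError(f"subjects missing from metadata: {missing}")
    extra = [s for s in groups if s not in set(subject_ids)]
    if extra:
        raise ValueError(f"metadata subjects not present in table: {extra}")


@dataclasses.dataclass
class CTTable:
    """Subjects x probes matrix of raw threshold-cycle values plus group labels.

    ``ct`` is a float matrix with NaN for missing (undetected) wells; finite
    values must lie in ``(0, CT_CEILING]``.
    """

    subject_ids: list[str]
    probe_ids: list[str]
    ct: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.ndim != 2:
            raise ValueError("ct must be a 2-D matrix")
        _check_ids(self.subject_ids, self.probe_ids,
                   self.ct.shape[0], self.ct.shape[1], self.groups)
        finite = self.ct[np.isfinite(self.ct)]
        if finite.size and (finite.min() <= 0 or finite.max() > CT_CEILING):
            raise ValueError(
                f"CT values must lie in (0, {CT_CEILING}]; "
                f"observed range [{finite.min()}, {finite.max()}]"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in table") from None

    def subjects_in(self, group_label: str) -> list[str]:
        return [s for s in self.subject_ids if self.groups[s] == group_label]


@dataclasses.dataclass
class ExpressionMatrix:
    """Subjects x probes matrix of reference-normalised relative expression.

    The reference probe is excluded; all finite levels are strictly positive.
    NaN marks levels that could not be computed (missing target CT).
    """

    subject_ids: list[str]
    probe_ids: list[str]
    levels: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D matrix")
        _check_ids(self.subject_ids, self.probe_ids,
                   self.levels.shape[0], self.levels.shape[1], self.groups)
        finite = self.levels[np.isfinite(self.levels)]
        if finite.size and finite.min() <= 0:
            raise ValueError("relative expression levels must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in expression matrix") from None

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"subject {subject_id!r} not in expression matrix") from None

    def subjects_in(self, group_label: str) -> list[str]:
        return [s for s in self.subject_ids if self.groups[s] == group_label]

    def group_mask(self, group_label: str) -> np.ndarray:
        return np.array([self.groups[s] == group_label for s in self.subject_ids])

    def subset(self, subject_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.subject_index(s) for s in subject_ids]
        return ExpressionMatrix(
            subject_ids=list(subject_ids),
            probe_ids=list(self.probe_ids),
            levels=self.levels[idx, :],
            groups={s: self.groups[s] for s in subject_ids},
        )


def _parse_ct_cell(raw: object, subject: str, probe: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text in MISSING_TOKENS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric CT value {text!r} for subject {subject!r}, probe {probe!r}"
        ) from None


def read_ct_table(path, metadata_path) -> CTTable:
    """Read a CT TSV plus its subject-metadata TSV into a :class:`CTTable`."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "subject_id":
        raise ValueError(
            f"first column of {path} must be 'subject_id', got {frame.columns[0]!r}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("subject_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata {metadata_path} lacks required column {col!r}")

    subject_ids = frame["subject_id"].tolist()
    probe_ids = [c for c in frame.columns if c != "subject_id"]
    ct = np.empty((len(subject_ids), len(probe_ids)))
    for i, subject in enumerate(subject_ids):
        for j, probe in enumerate(probe_ids):
            ct[i, j] = _parse_ct_cell(frame.iloc[i][probe], subject, probe)
    groups = dict(zip(meta["subject_id"], meta["group"]))
    bad = sorted({g for g in groups.values() if g not in GROUP_LABELS})
    if bad:
        raise ValueError(
            f"unknown group labels {bad}; allowed labels are {list(GROUP_LABELS)}"
        )
    return CTTable(subject_ids=subject_ids, probe_ids=probe_ids, ct=ct, groups=groups)


def write_ct_table(table: CTTable, path, metadata_path) -> None:
    """Write a :class:`CTTable` as the TSV pair read by :func:`read_ct_table`."""
    frame = pd.DataFrame(table.ct, columns=table.probe_ids)
    frame.insert(0, "subject_id", table.subject_ids)
    frame.to_csv(path, sep="\t", index=False, na_rep="")
    meta = pd.DataFrame({
        "subject_id": table.subject_ids,
        "group": [table.groups[s] for s in table.subject_ids],
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


def ct_to_relative(table: CTTable, reference_probe: str = "GAPDH") -> ExpressionMatrix:
    """Convert raw CTs to relative expression ``2**(ct[reference] - ct[target])``.

    The reference column is dropped from the output.  A missing reference CT is
    an error (nothing can be normalised for that subject); missing target CTs
    propagate as NaN levels.
    """
    ref_idx = table.probe_index(reference_probe)
    ref_ct = table.ct[:, ref_idx]
    bad = [s for s, v in zip(table.subject_ids, ref_ct) if not np.isfinite(v)]
    if bad:
        raise ValueError(
            f"reference probe {reference_probe!r} has missing CT for subjects: {bad}"
        )
    keep = [j for j in range(len(table.probe_ids)) if j != ref_idx]
    levels = 2.0 ** (ref_ct[:, None] - table.ct[:, keep])
    return ExpressionMatrix(
        subject_ids=list(table.subject_ids),
        probe_ids=[table.probe_ids[j] for j in keep],
        levels=levels,
        groups=dict(table.groups),
    )


def merge_labels(expr: ExpressionMatrix, mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Copy of ``expr`` with group labels rewritten (e.g. CD/UC -> IBD).

    Unmapped labels pass through unchanged.  Merged labels are in-memory
    analysis artifacts; files on disk keep the canonical cohort labels.
    """
    groups = {s: mapping.get(g, g) for s, g in expr.groups.items()}
    return ExpressionMatrix(
        subject_ids=list(expr.subject_ids), probe_ids=list(expr.probe_ids),
        levels=expr.levels.copy(), groups=groups,
    )


def ratio_value(expr: ExpressionMatrix, numerator_probe: str,
                denominator_probe: str, subject_id: str) -> float:
    """Expression ratio level[numerator]/level[denominator] for one subject.

    The reference probe cancels in this quotient, so the value equals
    ``2**(ct[denominator] - ct[numerator])`` regardless of normaliser choice.
    """
    i = expr.subject_index(subject_id)
    num = expr.levels[i, expr.probe_index(numerator_probe)]
    den = expr.levels[i, expr.probe_index(denominator_probe)]
    if not np.isfinite(den) or den <= 0:
        raise ValueError(
            f"denominator probe {denominator_probe!r} missing or nonpositive "
            f"for subject {subject_id!r}"
        )
    if not np.isfinite(num):
        raise ValueError(
            f"numerator probe {numerator_probe!r} missing for subject {subject_id!r}"
        )
    return float(num / den)
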