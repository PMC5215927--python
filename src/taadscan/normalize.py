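"""Reporter-activity normalization: pin a reference construct at 100%.

Raw β-galactosidase replicate measurements are rescaled so that the mean
of a chosen reference construct equals exactly 100%; means and sample
standard deviations (n−1 denominator, the usual estimator for triplicate
biological assays) are then computed on the rescaled replicates.  Only the
reference mean is pinned — its SD is scaled like everything else, not
zeroed.

The procedure is scale-equivariant (multiplying all raw values by any
positive constant changes nothing) and idempotent (normalizing an
already-normalized table is the identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd


class NormalizationConfigError(ValueError):
    """Raised for an unusable reference or inverted classification bands."""


@dataclass(frozen=True)
class ActivityTable:
    """Replicate activity measurements per construct, plus the reference.

    `rows` maps construct name to its replicate values (each ≥ 1 value,
    all non-negative); `reference_name` must be present with mean > 0.
    """

    rows: Mapping[str, tuple[float, ...]]
    reference_name: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("activity table has no constructs")
        for name, reps in self.rows.items():
            if len(reps) == 0:
                raise ValueError(f"construct {name!r} has no replicates")
            if any(v < 0 for v in reps):
                raise ValueError(f"construct {name!r} has negative activity")
        if self.reference_name not in self.rows:
            raise NormalizationConfigError(
                f"reference construct {self.reference_name!r} not in table"
            )
        if float(np.mean(self.rows[self.reference_name])) <= 0:
            raise NormalizationConfigError(
                f"reference construct {self.reference_name!r} has zero mean"
            )

    @classmethod
    def from_tsv(cls, source: IO[str], reference_name: str) -> "ActivityTable":
        """Read a TSV of ``construct<TAB>rep1<TAB>rep2...`` rows.

        A header line whose second field is not numeric is skipped.
        Constructs may have unequal replicate counts.
        """
        rows: dict[str, tuple[float, ...]] = {}
        for i, line in enumerate(source):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {i + 1}: expected construct + replicates")
            try:
                reps = tuple(float(v) for v in fields[1:] if v != "")
            except ValueError:
                if i == 0:
                    continue  # header
                raise ValueError(f"line {i + 1}: non-numeric replicate value")
            rows[fields[0]] = reps
        return cls(rows=rows, reference_name=reference_name)


def normalize(table: ActivityTable) -> pd.DataFrame:
    """Normalize replicate activities to the reference mean = 100%.

    Every replicate is multiplied by ``100 / mean(reference replicates)``
    before the per-construct mean and sample SD (ddof=1) are computed, so
    the reference SD is scaled rather than discarded.  A construct with a
    single replicate gets SD = NaN (the n−1 estimator is undefined).

    Returns a DataFrame indexed by construct with columns ``mean_pct``
    and ``sd_pct``, in table order; the reference row's mean is exactly
    100.
    """
    factor = 100.0 / float(np.mean(table.rows[table.reference_name]))
    out = {}
    for name, reps in table.rows.items():
        scaled = np.asarray(reps, dtype=float) * factor
        sd = float(np.std(scaled, ddof=1)) if len(scaled) > 1 else float("nan")
        out[name] = (float(scaled.mean()), sd)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["mean_pct", "sd_pct"])
    df.index.name = "construct"
    # exact pinning: the reference mean is 100 by construction up to rounding
    df.loc[table.reference_name, "mean_pct"] = 100.0
    return df


def classify(
    normalized: pd.DataFrame,
    basal_threshold: float = 10.0,
    strong_threshold: float = 50.0,
) -> pd.Series:
    """Assign {inactive, basal, strong} classes from normalized means.

    Half-open bands, lower-inclusive at the upper edge:
    mean < basal_threshold → ``inactive``; basal_threshold ≤ mean <
    strong_threshold → ``basal``; mean ≥ strong_threshold → ``strong``.
    The default thresholds (10% and 50% of the reference) are pragmatic
    reporting conventions, not measured quantities, and should be tuned
    per assay.
    """
    if not (0 <= basal_threshold < strong_threshold):
        raise NormalizationConfigError(
            f"thresholds must satisfy 0 <= basal < strong; got "
            f"{basal_threshold}, {strong_threshold}"
        )
    means = normalized["mean_pct"]
    labels = pd.Series("basal", index=normalized.index, name="class")
    labels[means < basal_threshold] = "inactive"
    labels[means >= strong_threshold] = "strong"
    return labels


def write_normalized_tsv(
    normalized: pd.DataFrame, classes: pd.Series | None = None
) -> str:
    """Render the normalized table (and optional classes) as TSV text."""
    df = normalized.copy()
    if classes is not None:
        df["class"] = classes
    return df.to_csv(sep="\t", float_format="%.6g")
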