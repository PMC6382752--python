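"""Class-inclusion rules applied before testing.

A class is kept when it is ever-present (strictly positive in every sample)
and reaches the minimum-proportion threshold in at least one sample.
Everything else is summed into an aggregate class; if the aggregate still
contains a zero (or is empty) it is deleted and each row renormalized.
Zeros would send the Dirichlet likelihood to zero, so the filtered table
never contains one. An optional zero-replacement escape hatch substitutes
a tiny value for every zero instead of filtering.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .composition import CompositionTable

__all__ = ["FilterSpec", "FilterReport", "filter_classes", "replace_zeros"]

logger = logging.getLogger(__name__)

DEFAULT_OTHER_LABEL = "LRT other"


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Options controlling class filtering.

    ``min_proportion`` is a proportion in [0, 1); e.g. a 1% threshold is
    0.01. The default 0 disables the threshold. ``zero_replacement``, when
    set (typically ~1e-16), replaces zeros instead of filtering on
    ever-presence.
    """

    min_proportion: float = 0.0
    require_ever_present: bool = True
    other_label: str = DEFAULT_OTHER_LABEL
    zero_replacement: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_proportion < 1.0):
            raise ValueError("min_proportion must lie in [0, 1)")
        if self.zero_replacement is not None and not (
            0.0 < self.zero_replacement <= 1e-6
        ):
            raise ValueError("zero_replacement must lie in (0, 1e-6]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class FilterReport:
    kept_classes: tuple[str, ...]
    aggregated_classes: tuple[str, ...]
    other_dropped: bool
    K_before: int
    K_after: int

    def to_dict(self) -> dict:
        return {
            "kept_classes": list(self.kept_classes),
            "aggregated_classes": list(self.aggregated_classes),
            "other_dropped": self.other_dropped,
            "K_before": self.K_before,
            "K_after": self.K_after,
        }

    def summary(self) -> str:
        lines = [
            f"classes before filtering: {self.K_before}",
            f"classes after filtering:  {self.K_after}",
            f"kept: {', '.join(self.kept_classes)}",
        ]
        if self.aggregated_classes:
            fate = "dropped" if self.other_dropped else "retained as aggregate"
            lines.append(
                f"aggregated ({fate}): {', '.join(self.aggregated_classes)}"
            )
        return "\n".join(lines)


def replace_zeros(table: CompositionTable, epsilon: float = 1e-16) -> CompositionTable:
    """Replace every zero entry by ``epsilon`` and renormalize rows.

    Results from analyses using this option should be quoted with extreme
    caution; a warning is emitted to that effect.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not table.is_normalized:
        raise ValueError("replace_zeros expects a normalized table")
    values = table.values.copy()
    n_zero = int((values == 0).sum())
    if n_zero == 0:
        return table
    warnings.warn(
        "zero entries replaced by a small value; results from tests "
        "exercising this option should be quoted with extreme caution",
        UserWarning,
        stacklevel=2,
    )
    values[values == 0] = epsilon
    values /= values.sum(axis=1, keepdims=True)
    return dataclasses.replace(table, values=values, is_normalized=True)


def filter_classes(
    table: CompositionTable, spec: FilterSpec | None = None
) -> tuple[CompositionTable, FilterReport]:
    """Apply the ever-present and minimum-proportion rules.

    Keeps a class iff it is positive in every sample (unless ever-presence
    is waived) AND its maximum proportion over samples reaches
    ``min_proportion``. All failing classes are summed column-wise into the
    aggregate; an aggregate with any zero sample (or no members) is deleted
    and rows renormalized. The output has no zero entries and rows summing
    to 1 within 1e-9.
    """
    spec = spec or FilterSpec()
    if not table.is_normalized:
        raise ValueError("filter_classes expects a normalized table")

    if spec.zero_replacement is not None:
        # Zero replacement exists to retain zero-bearing classes, so it
        # supersedes the ever-present requirement.
        table = replace_zeros(table, spec.zero_replacement)

    values = table.values
    ever_present = np.all(values > 0, axis=0)
    reaches_threshold = values.max(axis=0) >= spec.min_proportion
    keep = reaches_threshold.copy()
    if spec.require_ever_present and spec.zero_replacement is None:
        keep &= ever_present

    kept_names = tuple(c for c, k in zip(table.class_names, keep) if k)
    agg_names = tuple(c for c, k in zip(table.class_names, keep) if not k)
    if not kept_names:
        raise ValueError("all classes failed the filter; nothing to test")

    kept_values = values[:, keep]
    other = values[:, ~keep].sum(axis=1)

    other_dropped = True
    if agg_names and np.all(other > 0):
        out_values = np.column_stack([kept_values, other])
        out_names = kept_names + (spec.other_label,)
        other_dropped = False
    else:
        # aggregate empty or zero-bearing: delete and renormalize
        out_values = kept_values / kept_values.sum(axis=1, keepdims=True)
        out_names = kept_names

    if len(out_names) < 3:
        raise ValueError(
            f"only {len(out_names)} classes survive filtering; the Dirichlet "
            "test needs more than 2"
        )

    report = FilterReport(
        kept_classes=kept_names,
        aggregated_classes=agg_names,
        other_dropped=other_dropped if agg_names else True,
        K_before=table.n_classes,
        K_after=len(out_names),
    )
    logger.info("class filter: %s", report.summary().replace("\n", "; "))

    out = dataclasses.replace(
        table,
        class_names=out_names,
        values=out_values,
        is_normalized=True,
    )
    return out, report
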