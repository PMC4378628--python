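"""Relative expression per gene and per subfamily.

Tissue mode expresses each value relative to the gene's mean over all
tissues, log2(x_t / mean(x)); stress mode relative to the mapped control,
log2(treatment / control).  Subfamily profiles average the NORMALIZED
intensities across measured members first, then apply the relative
transform — the order the underlying study states.  A subfamily enters the
analysis only when at least one third of its members are measured
(boundary inclusive).

Replicate conditions sharing a label are mean-collapsed before any relative
transform.  A floor of 1e-6 on intensities prevents log-of-zero; floored
values are carried, not dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable

EPSILON = 1e-6


def collapse_replicates(table: ExpressionTable) -> pd.DataFrame:
    """Mean-collapse replicate condition columns that share a label.

    Output columns are the distinct labels, in first-appearance order.
    """
    labels = [table.condition_labels[c] for c in table.values.columns]
    collapsed = table.values.T.groupby(labels, sort=False).mean().T
    return collapsed


def relative_expression_tissue(x: pd.Series | np.ndarray, log2: bool = True) -> np.ndarray:
    """log2 of each tissue value over the across-tissue mean of the gene."""
    values = np.asarray(x, dtype=float)
    if np.all(values == 0):
        warnings.warn("all-zero expression vector; relative values undefined",
                      stacklevel=2)
        return np.full(values.shape, np.nan)
    floored = np.maximum(values, EPSILON)
    ratio = floored / floored.mean()
    return np.log2(ratio) if log2 else ratio


def relative_expression_stress(
    x: pd.Series,
    control_map: Mapping[str, str],
    log2: bool = True,
) -> pd.Series:
    """log2(treatment / control) per the treatment->control map.

    The result is indexed by the treatment conditions, in map-sorted order.
    """
    out = {}
    for treatment in sorted(control_map):
        control = control_map[treatment]
        if treatment not in x.index:
            raise KeyError(f"treatment condition {treatment!r} missing")
        if control not in x.index:
            raise KeyError(f"control condition {control!r} missing")
        t = max(float(x[treatment]), EPSILON)
        c = max(float(x[control]), EPSILON)
        ratio = t / c
        out[treatment] = np.log2(ratio) if log2 else ratio
    return pd.Series(out)


@dataclass
class SubfamilyProfile:
    subfamily: str
    conditions: list[str]
    values: np.ndarray
    measured_members: int
    total_members: int
    included: bool

    @property
    def measured_fraction(self) -> float:
        return self.measured_members / self.total_members


def aggregate_subfamily(
    table: ExpressionTable,
    members: Mapping[str, Sequence[str]],
    mode: str = "tissue",
    min_fraction_numerator: int = 1,
    min_fraction_denominator: int = 3,
) -> list[SubfamilyProfile]:
    """Per-subfamily averaged relative expression with the one-third rule.

    Normalized intensities are averaged across measured members, then the
    mode's relative transform is applied.  ``included`` is true when
    measured/total >= 1/3 (inclusive; compared in exact integer arithmetic).
    Subfamily members missing from the table count as unmeasured.
    """
    if mode not in {"tissue", "stress"}:
        raise ValueError(f"unknown mode {mode!r}")
    profiles = []
    measured_genes = set(table.values.index)
    collapsed = collapse_replicates(table)
    for subfamily in sorted(members):
        gene_list = list(members[subfamily])
        if not gene_list:
            warnings.warn(f"subfamily {subfamily} has no members; skipped",
                          stacklevel=2)
            continue
        measured = sorted(set(gene_list) & measured_genes)
        total = len(gene_list)
        included = min_fraction_denominator * len(measured) >= min_fraction_numerator * total
        if measured:
            mean_profile = collapsed.loc[measured].mean(axis=0)
            if mode == "tissue":
                values = relative_expression_tissue(mean_profile.to_numpy())
                conditions = list(collapsed.columns)
            else:
                if table.control_map is None:
                    raise ValueError("stress mode requires a control map")
                rel = relative_expression_stress(mean_profile, table.control_map)
                values = rel.to_numpy()
                conditions = list(rel.index)
        else:
            if mode == "stress" and table.control_map is not None:
                conditions = sorted(table.control_map)
            else:
                conditions = list(collapsed.columns)
            values = np.full(len(conditions), np.nan)
        profiles.append(SubfamilyProfile(
            subfamily=subfamily,
            conditions=conditions,
            values=values,
            measured_members=len(measured),
            total_members=total,
            included=included,
        ))
    return profiles


def profiles_matrix(profiles: Sequence[SubfamilyProfile]) -> pd.DataFrame:
    """Heat-map-ready matrix (rows = subfamilies, columns = conditions)."""
    if not profiles:
        return pd.DataFrame()
    conditions = profiles[0].conditions
    data = {p.subfamily: p.values for p in profiles}
    return pd.DataFrame(data, index=conditions).T


def write_profiles_tsv(profiles: Sequence[SubfamilyProfile], path: str | Path) -> None:
    profiles_matrix(profiles).to_csv(path, sep="\t", float_format="%.6g",
                                     index_label="subfamily")


def write_inclusion_tsv(profiles: Sequence[SubfamilyProfile], path: str | Path) -> None:
    lines = ["subfamily\tmeasured\ttotal\tincluded"]
    for p in sorted(profiles, key=lambda p: p.subfamily):
        lines.append(f"{p.subfamily}\t{p.measured_members}\t{p.total_members}\t"
                     f"{int(p.included)}")
    Path(path).write_text("\n".join(lines) + "\n")
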