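"""Dichotomous survival trait: survival to 85+ (case) versus death or last
follow-up between 75 and 85 (control); younger individuals are excluded.

An individual alive at last follow-up with age in [75, 85) is a control,
even though they may yet survive past 85; an individual whose age is
already >= 85 demonstrates survival to 85 whether or not a death age is
recorded.  ``exclude_alive_controls`` drops alive-censored controls for a
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .simulate import PhenotypeRecord

__all__ = ["SurvivalTraitConfig", "assign_class", "build_cohort", "CohortError"]

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


class CohortError(ValueError):
    pass


@dataclass
class SurvivalTraitConfig:
    case_min_age: float = 85.0
    control_min_age: float = 75.0
    control_max_age_exclusive: float = 85.0
    exclude_alive_controls: bool = False

    def __post_init__(self) -> None:
        if not (
            self.control_min_age
            < self.control_max_age_exclusive
            <= self.case_min_age
        ):
            raise ValueError(
                "need control_min_age < control_max_age_exclusive <= case_min_age"
            )


def assign_class(rec: PhenotypeRecord, cfg: SurvivalTraitConfig) -> str:
    """Map one record to case / control / excluded."""
    age = rec.lifespan_or_last_age
    if age <= 0:
        raise ValueError(f"non-positive age for {rec.individual_id}")
    if age >= cfg.case_min_age:
        return CASE
    if cfg.control_min_age <= age < cfg.control_max_age_exclusive:
        if cfg.exclude_alive_controls and not rec.died:
            return EXCLUDED
        return CONTROL
    return EXCLUDED


def build_cohort(
    records: Iterable[PhenotypeRecord],
    cfg: SurvivalTraitConfig,
    individual_ids: Sequence[str] | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label the cohort and produce a summary table.

    Returns ``(labels, summary)``: ``labels`` is a 0/1 Series (1 = case)
    indexed by individual_id covering cases and controls only; excluded
    individuals are absent.  If ``individual_ids`` (e.g. the genotyped
    set) is given, every one of them must have a phenotype record, and
    the labels are restricted to (and ordered by) that set.

    ``summary`` is a per-class table (N; % education, % ever smoked,
    split by sex when covariates are supplied).
    """
    recs = {r.individual_id: r for r in records}
    if individual_ids is not None:
        missing = [i for i in individual_ids if i not in recs]
        if missing:
            raise CohortError(
                f"{len(missing)} genotyped individuals lack phenotype records: "
                + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else "")
            )
        ordered = [recs[i] for i in individual_ids]
    else:
        ordered = list(recs.values())

    classes = {r.individual_id: assign_class(r, cfg) for r in ordered}
    labels = pd.Series(
        {i: 1 if c == CASE else 0 for i, c in classes.items() if c != EXCLUDED},
        dtype=int,
        name="label",
    )
    if individual_ids is not None:
        keep = [i for i in individual_ids if classes[i] != EXCLUDED]
        labels = labels.loc[keep]
    labels.index.name = "individual_id"

    rows = []
    groups: list[tuple[str, pd.Index]] = [("total", labels.index)]
    if covariates is not None and "sex" in covariates.columns:
        sex = covariates.loc[labels.index, "sex"]
        groups += [
            ("male", labels.index[sex == 0]),
            ("female", labels.index[sex == 1]),
        ]
    for group, idx in groups:
        sub = labels.loc[idx]
        for cls, val in ((CASE, 1), (CONTROL, 0)):
            members = sub.index[sub == val]
            row = {"group": group, "class": cls, "N": len(members)}
            if covariates is not None:
                for cov in ("education", "smoking"):
                    if cov in covariates.columns and len(members):
                        row[f"pct_{cov}"] = round(
                            100.0 * covariates.loc[members, cov].mean(), 2
                        )
            rows.append(row)
    n_excluded = sum(1 for c in classes.values() if c == EXCLUDED)
    summary = pd.DataFrame(rows)
    summary.attrs["n_excluded"] = n_excluded
    return labels, summary
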