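"""Respiratory mechanics, best-PEEP titration, hysteresis and imputation.

Static elastances follow the two-point method from paired end-inspiratory /
end-expiratory occlusion pressures:

    E_rs = (P_aw,insp - P_aw,exp) / V_T        respiratory system
    E_W  = (P_es,insp - P_es,exp) / V_T        chest wall (esophageal)
    E_L  = E_rs - E_W                          lung

so E_rs = E_W + E_L holds by construction.  Transpulmonary pressure is
airway minus esophageal pressure at matching phase, and the P/F ratio is
PaO2/FiO2 (mmHg); P/F < 300 mmHg marks lung injury.

Best PEEP for a titration target (e.g. lowest E_rs, highest P/F) is the
arg-extremum over the descending-phase PEEP ladder of the per-PEEP median;
ties resolve to the lowest PEEP, the clinically conservative choice.

Missing cells are imputed from the average relative difference between the
affected subject and the other subjects: for subject s missing endpoint e
in cell j,  imputed = mean_others(e at j) * r_s,  where r_s is the mean of
e_s(j') / mean_others(e at j') over the cells j' where s was observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTOCOL_PEEPS",
    "INJURY_PF_THRESHOLD",
    "MechanicsRecord",
    "BestPeepResult",
    "HysteresisResult",
    "derive_mechanics",
    "classify_injury",
    "best_peep",
    "hysteresis",
    "impute_missing",
    "mechanics_table",
]

#: PEEP ladder of the titration protocol (cmH2O).
PROTOCOL_PEEPS = (5.0, 12.0, 17.0, 22.0, 27.0)

#: P/F ratio below which lungs are classified as injured (mmHg).
INJURY_PF_THRESHOLD = 300.0

TABLE_COLUMNS = ["subject", "condition", "phase", "peep_cmH2O", "endpoint", "value"]


@dataclass(frozen=True)
class MechanicsRecord:
    """One ventilatory measurement set; derived fields filled by
    :func:`derive_mechanics`.

    Pressures in cmH2O, tidal volume ``v_t`` in L, PaO2 in mmHg, FiO2 as a
    fraction.  ``p_aw_exp`` is the *total* end-expiratory airway pressure
    (set PEEP plus intrinsic PEEP when measured).
    """

    p_aw_insp: float
    p_aw_exp: float
    p_es_insp: float
    p_es_exp: float
    v_t: float
    pao2: float | None = None
    fio2: float | None = None
    e_rs: float | None = None
    e_w: float | None = None
    e_l: float | None = None
    p_l_insp: float | None = None
    p_l_exp: float | None = None
    pf_ratio: float | None = None


@dataclass(frozen=True)
class BestPeepResult:
    """Winning PEEP for one titration target."""

    target: str
    direction: str
    peep_cmH2O: float
    value: float
    tie: bool


@dataclass(frozen=True)
class HysteresisResult:
    """Descending-minus-ascending deltas and their per-PEEP summaries."""

    deltas: pd.DataFrame  # subject, condition, endpoint, peep_cmH2O, delta
    summary: pd.DataFrame  # condition, endpoint, peep_cmH2O, median, q1, q3
    skipped: tuple[tuple, ...]  # cells missing one of the two phases


def derive_mechanics(record: MechanicsRecord) -> MechanicsRecord:
    """Fill elastances, transpulmonary pressures and the P/F ratio."""
    if record.v_t <= 0:
        raise ValueError(f"tidal volume must be > 0 L, got {record.v_t}")
    if record.fio2 is not None and not (0.0 < record.fio2 <= 1.0):
        raise ValueError(f"FiO2 must be in (0, 1], got {record.fio2}")
    e_rs = (record.p_aw_insp - record.p_aw_exp) / record.v_t
    e_w = (record.p_es_insp - record.p_es_exp) / record.v_t
    pf = None
    if record.pao2 is not None and record.fio2 is not None:
        pf = record.pao2 / record.fio2
    return replace(
        record,
        e_rs=e_rs,
        e_w=e_w,
        e_l=e_rs - e_w,
        p_l_insp=record.p_aw_insp - record.p_es_insp,
        p_l_exp=record.p_aw_exp - record.p_es_exp,
        pf_ratio=pf,
    )


def classify_injury(pf_ratio: float) -> bool:
    """True iff the P/F ratio indicates lung injury (strictly < 300 mmHg)."""
    if pf_ratio < 0:
        raise ValueError(f"P/F ratio must be >= 0, got {pf_ratio}")
    return pf_ratio < INJURY_PF_THRESHOLD


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"titration table lacks columns {missing}")


def best_peep(
    table: pd.DataFrame,
    target: str,
    direction: str,
    condition: str | None = None,
) -> BestPeepResult:
    """Select the optimum PEEP for one endpoint on the descending phase.

    The endpoint's per-PEEP median (across subjects) is extremized:
    ``direction`` is ``"highest"`` or ``"lowest"``.  Equal-value ties
    resolve to the lowest PEEP with ``tie=True``.  Every PEEP level present
    in the (filtered) table must carry a value; a hole raises and names the
    cell, pointing at :func:`impute_missing`.
    """
    _check_table(table)
    if direction not in ("highest", "lowest"):
        raise ValueError(f"direction must be 'highest' or 'lowest', got {direction!r}")
    sub = table[table["phase"] == "descending"]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    elif sub["condition"].nunique() > 1:
        raise ValueError(
            f"table mixes conditions {sorted(sub['condition'].unique())}; pass condition="
        )
    peeps = sorted(sub["peep_cmH2O"].unique())
    if not peeps:
        raise ValueError("no descending-phase rows in the table")
    sub = sub[sub["endpoint"] == target]
    per_peep = sub.groupby("peep_cmH2O")["value"].median()
    for peep in peeps:
        if peep not in per_peep.index or not np.isfinite(per_peep.get(peep, np.nan)):
            raise ValueError(
                f"endpoint {target!r} has no value at PEEP {peep} cmH2O; "
                "impute or complete the table first"
            )
    values = per_peep.loc[peeps]
    extremum = values.max() if direction == "highest" else values.min()
    winners = [p for p in peeps if values.loc[p] == extremum]
    return BestPeepResult(
        target=target,
        direction=direction,
        peep_cmH2O=float(min(winners)),
        value=float(extremum),
        tie=len(winners) > 1,
    )


def hysteresis(table: pd.DataFrame) -> HysteresisResult:
    """Descending-minus-ascending difference for every measured cell.

    Cells with only one phase are skipped and reported, never silently
    dropped.  The summary gives median and quartiles of the deltas per
    (condition, endpoint, PEEP).
    """
    _check_table(table)
    keys = ["subject", "condition", "endpoint", "peep_cmH2O"]
    wide = table.pivot_table(
        index=keys, columns="phase", values="value", aggfunc="first"
    ).reset_index()
    for phase in ("ascending", "descending"):
        if phase not in wide.columns:
            wide[phase] = np.nan
    ok = wide["ascending"].notna() & wide["descending"].notna()
    skipped = tuple(map(tuple, wide.loc[~ok, keys].itertuples(index=False, name=None)))
    deltas = wide.loc[ok, keys].copy()
    deltas["delta"] = (wide.loc[ok, "descending"] - wide.loc[ok, "ascending"]).to_numpy()
    summary = (
        deltas.groupby(["condition", "endpoint", "peep_cmH2O"])["delta"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return HysteresisResult(deltas=deltas, summary=summary, skipped=skipped)


def impute_missing(table: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple]]:
    """Fill missing cells from average relative subject-vs-others differences.

    Operates per endpoint.  A cell is a (condition, phase, peep) triple.
    For subject s missing endpoint e at cell j the imputed value is
    ``mean_others(e at j) * r_s`` with ``r_s`` the mean over s's observed
    cells j' of ``e_s(j') / mean_others(e at j')``.  Cells whose
    preconditions fail (no other subject observed at j, or s observed
    nowhere for e) stay missing and are returned in the report list.

    The rule is a no-op on complete tables and scale-equivariant per
    endpoint.
    """
    _check_table(table)
    out = table.copy()
    report: list[tuple] = []
    cell_keys = ["condition", "phase", "peep_cmH2O"]

    for endpoint, grp in table.groupby("endpoint"):
        if not grp["value"].isna().any():
            continue
        # mean over *other* subjects per cell, for each subject
        for idx in grp.index[grp["value"].isna()]:
            row = table.loc[idx]
            s = row["subject"]
            others = grp[(grp["subject"] != s) & grp["value"].notna()]
            others_at_j = others
            for k in cell_keys:
                others_at_j = others_at_j[others_at_j[k] == row[k]]
            own = grp[(grp["subject"] == s) & grp["value"].notna()]
            if others_at_j.empty or own.empty:
                report.append((s, endpoint, row["condition"], row["phase"], row["peep_cmH2O"]))
                continue
            ratios = []
            for _, orow in own.iterrows():
                peers = others
                for k in cell_keys:
                    peers = peers[peers[k] == orow[k]]
                if not peers.empty:
                    ratios.append(orow["value"] / peers["value"].mean())
            if not ratios:
                report.append((s, endpoint, row["condition"], row["phase"], row["peep_cmH2O"]))
                continue
            r_s = float(np.mean(ratios))
            out.loc[idx, "value"] = float(others_at_j["value"].mean()) * r_s
    return out, report


def mechanics_table(
    records: Sequence[tuple[str, str, str, float, MechanicsRecord]],
) -> pd.DataFrame:
    """Tidy titration table from (subject, condition, phase, peep, record) rows.

    Derives each record first; exports one long-format row per endpoint so
    the result feeds :func:`best_peep`, :func:`hysteresis` and any external
    statistics package directly.
    """
    rows = []
    for subject, condition, phase, peep, rec in records:
        filled = derive_mechanics(rec)
        endpoints = {
            "elastance_rs": filled.e_rs,
            "elastance_cw": filled.e_w,
            "elastance_lung": filled.e_l,
            "transpulmonary_insp": filled.p_l_insp,
            "transpulmonary_exp": filled.p_l_exp,
            "pf_ratio": filled.pf_ratio,
        }
        for endpoint, value in endpoints.items():
            if value is None:
                continue
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "phase": phase,
                    "peep_cmH2O": float(peep),
                    "endpoint": endpoint,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
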