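"""Dissociation-constant ↔ binding-free-energy conversions with error propagation.

The bridge between measured affinities and computed binding energies is

    ΔG = RT ln(K_D)        (K_D in molar; RT defaults to 0.593 kcal/mol, 298 K)

with the uncertainty propagated as

    σ_ΔG = 0.434 (σ_KD / K_D)

where 0.434 is log10(e) — the relative K_D error mapped onto a log10 scale.
This error formula is applied verbatim as the source analysis defines it; note
it omits the 2.303·RT factor a natural-log propagation in kcal/mol would carry
(see the methods note).

A sub-molar K_D gives a negative (favorable) ΔG; published summaries often
quote the magnitude.  ``RT_ROOM`` (0.593) follows from R·298 K; the rounded
``RT = 0.6`` reproduces some printed 2-decimal figures and is accepted
everywhere ``rt`` is a parameter.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

#: RT at room temperature (kcal/mol) used for K_D → ΔG conversion.
RT_ROOM = 0.593

#: log10(e); the verbatim constant of the σ_ΔG propagation formula.
LOG10_E_COEFF = 0.434

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "μM": 1e-6,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

#: Table markers for affinities that could not be quantified.
NON_QUANTIFIABLE = ("CBE", "No binding")


class UnitError(ValueError):
    """Missing or unrecognized concentration unit."""


@dataclass(frozen=True)
class AffinityRecord:
    """An experimental K_D (molar) with uncertainty and its ΔG conversion."""

    name: str
    kd: float
    sigma_kd: float
    delta_g: float
    sigma_delta_g: float
    rt: float


def delta_g_from_kd(kd: float, rt: float = RT_ROOM) -> float:
    """ΔG = rt·ln(kd), kd in molar. Negative for sub-molar kd."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0 molar, got {kd}")
    return rt * math.log(kd)


def kd_from_delta_g(delta_g: float, rt: float = RT_ROOM) -> float:
    """Exact inverse of :func:`delta_g_from_kd`."""
    return math.exp(delta_g / rt)


def sigma_delta_g(kd: float, sigma_kd: float) -> float:
    """σ_ΔG = 0.434·(σ_kd/kd), the verbatim propagation rule."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0 molar, got {kd}")
    if sigma_kd < 0:
        raise ValueError(f"sigma_kd must be >= 0, got {sigma_kd}")
    return LOG10_E_COEFF * (sigma_kd / kd)


def parse_kd(text: str) -> float:
    """Parse a concentration with unit suffix ("72 μM", "1 M") into molar.

    The unit is mandatory: a bare number raises :class:`UnitError`, as does an
    unknown suffix.
    """
    match = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([A-Za-zμ]*)\s*", str(text))
    if not match:
        raise UnitError(f"cannot parse concentration {text!r}")
    value_text, unit = match.groups()
    try:
        value = float(value_text)
    except ValueError:
        raise UnitError(f"cannot parse concentration {text!r}") from None
    if not unit:
        raise UnitError(f"missing concentration unit in {text!r}")
    if unit not in _UNIT_TO_MOLAR:
        raise UnitError(
            f"unknown concentration unit {unit!r} "
            f"(expected one of {sorted(set(_UNIT_TO_MOLAR))})"
        )
    return value * _UNIT_TO_MOLAR[unit]


def make_affinity_record(
    name: str, kd_text: str, sigma_kd_text: str, rt: float = RT_ROOM
) -> AffinityRecord:
    kd = parse_kd(kd_text)
    sigma = parse_kd(sigma_kd_text) if str(sigma_kd_text).strip() else 0.0
    return AffinityRecord(
        name=name,
        kd=kd,
        sigma_kd=sigma,
        delta_g=delta_g_from_kd(kd, rt),
        sigma_delta_g=sigma_delta_g(kd, sigma),
        rt=rt,
    )


def read_affinity_table(
    path: str | Path, rt: float = RT_ROOM, sep: str = "\t"
) -> tuple[list[AffinityRecord], pd.DataFrame]:
    """Read a delimited affinity table into records plus excluded rows.

    Expected columns: ``peptide``, ``kd`` (value with unit, e.g. "72 uM"),
    ``sigma_kd``; extra columns pass through.  Rows whose ``kd`` is a
    non-quantifiable marker ("CBE", "No binding") are returned separately in
    the excluded-rows frame rather than converted.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    required = {"peptide", "kd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity table missing columns: {sorted(missing)}")
    records = []
    excluded_rows = []
    for _, row in df.iterrows():
        kd_text = str(row["kd"]).strip()
        if kd_text in NON_QUANTIFIABLE:
            excluded_rows.append(row)
            continue
        records.append(
            make_affinity_record(
                row["peptide"], kd_text, str(row.get("sigma_kd", "") or ""), rt
            )
        )
    excluded = (
        pd.DataFrame(excluded_rows).reset_index(drop=True)
        if excluded_rows
        else df.iloc[0:0]
    )
    return records, excluded


def compare_theory_experiment(
    be_table: pd.DataFrame,
    affinity_records: list[AffinityRecord],
) -> tuple[pd.DataFrame, float]:
    """Join computed BE values with measured ΔG and report their Pearson r.

    ``be_table`` needs columns ``peptide``, ``be``, ``err``.  Only peptides
    present in both tables with finite values enter the join; at least two are
    required.  Returns the joined per-peptide frame and the correlation of
    (be, ΔG) over it.
    """
    aff = pd.DataFrame(
        {
            "peptide": [r.name for r in affinity_records],
            "delta_g": [r.delta_g for r in affinity_records],
            "sigma_delta_g": [r.sigma_delta_g for r in affinity_records],
        }
    )
    joined = be_table.merge(aff, on="peptide", how="inner")
    joined = joined[joined[["be", "delta_g"]].notna().all(axis=1)].reset_index(
        drop=True
    )
    if len(joined) < 2:
        raise ValueError(
            f"need >= 2 overlapping peptides with finite values, got {len(joined)}"
        )
    r = float(stats.pearsonr(joined["be"], joined["delta_g"]).statistic)
    return joined, r
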