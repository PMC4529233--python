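"""Accessors for the packaged MBP reference tables.

These are literature-reported values for the MBP-targeting octapeptide
campaign (docking-score table, SPR affinity table, candidate sequences),
shipped for tests and demos.  They are reference data — nothing in this
package regenerates them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .sequence import Peptide, read_fasta
from .thermo import AffinityRecord, RT_ROOM, read_affinity_table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pepmc").joinpath("data", name)))


def docking_scores() -> pd.DataFrame:
    """Reference docking-score table (13 candidates; kcal/mol).

    Columns: peptide, sequence, then mean/sd pairs for the single-shot
    protocol at the open binding site and the MC rescoring protocol at the
    open (binding) and closed (control) sites.
    """
    return pd.read_csv(_data_path("mbp_docking_scores.tsv"), sep="\t", comment="#")


def reference_be_table() -> pd.DataFrame:
    """BE computed from the reference MC rescoring means (binding − control)."""
    df = docking_scores()
    out = df[["peptide", "sequence"]].copy()
    out["be"] = df["mc_vina_open_mean"] - df["mc_vina_closed_mean"]
    # Reference sds are over all 100 retained samples; the matching SEM sum.
    out["err"] = (df["mc_vina_open_sd"] + df["mc_vina_closed_sd"]) / 10.0
    return out


def affinities(rt: float = RT_ROOM) -> tuple[list[AffinityRecord], pd.DataFrame]:
    """Reference SPR affinities converted to ΔG, plus the non-quantifiable rows."""
    return read_affinity_table(_data_path("mbp_affinities.tsv"), rt=rt)


def candidate_peptides() -> list[tuple[str, Peptide]]:
    """The 13 candidate octapeptides as (name, Peptide) pairs."""
    return read_fasta(_data_path("mbp_candidates.fasta"))


def candidates_fasta_path() -> Path:
    return _data_path("mbp_candidates.fasta")


def affinities_path() -> Path:
    return _data_path("mbp_affinities.tsv")
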