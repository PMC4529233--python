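"""TSV/FASTA writers for campaign outputs.

Every output file opens with comment headers carrying the tool version, a
stable hash of the configuration, and the campaign seed, so a result file is
traceable to the exact run that produced it.  Floats are written with
repr-roundtrip precision so identical runs yield byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .engine import CampaignResult, TRAJECTORY_COLUMNS, Trajectory
from .rescoring import BEResult
from .sequence import write_fasta
from .thermo import AffinityRecord


def _header(config_hash: str, seed: int, extra: dict | None = None) -> list[str]:
    lines = [
        f"# pepmc {__version__}",
        f"# config_hash={config_hash}",
        f"# seed={seed}",
    ]
    for key, value in (extra or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_trajectories(
    path: str | Path,
    trajectories: Sequence[Trajectory],
    config_hash: str = "",
    seed: int = 0,
) -> None:
    """All runs' per-step records as one TSV (run, step, replica, kBT, ...)."""
    lines = _header(config_hash, seed)
    lines.append("\t".join(TRAJECTORY_COLUMNS))
    for traj in trajectories:
        for run, step, replica, kBT, move, sequence, score, accepted in traj.records:
            lines.append(
                f"{run}\t{step}\t{replica}\t{kBT!r}\t{move}\t{sequence}\t"
                f"{score!r}\t{int(accepted)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_selected_fasta(
    path: str | Path,
    result: CampaignResult,
    config_hash: str = "",
    seed: int = 0,
) -> None:
    """Selected (lowest end-score) peptide of each run as FASTA records."""
    peptides = [s.peptide for s in result.selected]
    names = [f"run{s.run_index}" for s in result.selected]
    metadata = [
        {
            "score": repr(s.score),
            "kBT": repr(s.kBT),
            "config_hash": config_hash,
            "seed": seed,
        }
        for s in result.selected
    ]
    write_fasta(path, peptides, names=names, metadata=metadata)


def write_be_table(
    path: str | Path,
    ranked: Sequence[tuple[BEResult, bool]],
    config_hash: str = "",
    seed: int = 0,
) -> None:
    """Ranked per-peptide BE table (site means, SEMs, BE, error, overlap flag)."""
    lines = _header(config_hash, seed)
    lines.append(
        "rank\tpeptide\tsequence\tmean_binding\tsem_binding\t"
        "mean_control\tsem_control\tbe\terr\tunresolved_vs_best"
    )
    for rank, (r, flagged) in enumerate(ranked, start=1):
        name = r.name or r.peptide.sequence
        lines.append(
            f"{rank}\t{name}\t{r.peptide.sequence}\t{r.mean_binding!r}\t"
            f"{r.sem_binding!r}\t{r.mean_control!r}\t{r.sem_control!r}\t"
            f"{r.be!r}\t{r.err!r}\t{int(flagged)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_affinity_table(
    path: str | Path,
    records: Sequence[AffinityRecord],
    excluded: pd.DataFrame | None = None,
    config_hash: str = "",
    seed: int = 0,
) -> None:
    """Converted affinity records as TSV; excluded rows listed in the header."""
    extra = {}
    if excluded is not None and len(excluded):
        marks = ", ".join(
            f"{row['peptide']} ({row['kd']})" for _, row in excluded.iterrows()
        )
        extra["excluded_non_quantifiable"] = marks
    lines = _header(config_hash, seed, extra)
    lines.append("peptide\tkd_molar\tsigma_kd_molar\tdelta_g\tsigma_delta_g\trt")
    for r in records:
        lines.append(
            f"{r.name}\t{r.kd!r}\t{r.sigma_kd!r}\t{r.delta_g!r}\t"
            f"{r.sigma_delta_g!r}\t{r.rt!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
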