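"""Scoring backends: the contract the optimizer talks to, and the synthetic landscape.

The optimization engine never sees molecular structures.  A backend maps a
peptide sequence to one stochastic docking-like score sample (kcal/mol, more
negative = better predicted binding) plus an opaque pose handle — the
"relax + dock" stage of a docking pipeline collapses behind this call.

Two site labels exist: ``"binding"`` (the designated binding site) and
``"control"`` (a negative-control site experimentally shown not to bind),
because the corrected binding energy is the difference of the two means.

The synthetic landscape backend makes the whole tool testable without a
docking engine: a deterministic per-(position, residue) additive score table
(optionally with pairwise epistasis), Gaussian per-call noise, and a control
site modelled either as a constant offset or an independent table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .sequence import CANONICAL_AA, Peptide, _canonical_alphabet

SITE_BINDING = "binding"
SITE_CONTROL = "control"
SITE_LABELS = (SITE_BINDING, SITE_CONTROL)


class BackendFailure(RuntimeError):
    """A backend produced no pose/score; callers treat this as a rejected proposal."""


@dataclass(frozen=True)
class ScoreSample:
    """One docking-score observation.

    ``value`` is in kcal/mol; ``site_label`` is ``"binding"`` or ``"control"``;
    ``pose_id`` is a fresh opaque handle per call; ``step_index``/``run_index``
    locate the sample inside a campaign (−1 when not applicable).
    """

    value: float
    site_label: str
    pose_id: str
    step_index: int = -1
    run_index: int = -1

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError(f"score must be finite, got {self.value}")
        if self.site_label not in SITE_LABELS:
            raise ValueError(
                f"site_label must be one of {SITE_LABELS}, got {self.site_label!r}"
            )


@dataclass(frozen=True)
class DockingConfig:
    """Docking search-box metadata, passed verbatim to external adapters.

    Mirrors the grid parameters a docking engine expects (box centred on the
    target site, exhaustiveness, energy window).  The synthetic backend
    ignores everything except ``site_label``.
    """

    site_label: str = SITE_BINDING
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box_size: tuple[float, float, float] = (25.0, 25.0, 25.0)
    exhaustiveness: int = 10
    energy_range: float = 4.0
    receptor_path: str | None = None

    def __post_init__(self):
        if self.site_label not in SITE_LABELS:
            raise ValueError(
                f"site_label must be one of {SITE_LABELS}, got {self.site_label!r}"
            )
        if any(s <= 0 for s in self.box_size):
            raise ValueError(f"box_size components must be > 0, got {self.box_size}")


class ScoringBackend(Protocol):
    """Contract every backend satisfies.

    ``score`` returns one :class:`ScoreSample` or raises
    :class:`BackendFailure`; the engine maps failures to proposal rejections
    (a docking loop has no failure branch of its own).
    """

    alphabet: str

    def score(
        self,
        p: Peptide,
        config: DockingConfig,
        rng: np.random.Generator,
        step_index: int = -1,
        run_index: int = -1,
    ) -> ScoreSample: ...


# ---------------------------------------------------------------------------
# Synthetic landscape


@dataclass
class SyntheticLandscape:
    """Additive (optionally epistatic) score landscape with Gaussian noise.

    ``table[pos, res_index]`` holds the additive term (kcal/mol) of residue
    ``alphabet[res_index]`` at ``pos`` for the binding site.  The control site
    is either ``binding mean + control_offset`` or, when ``control_table`` is
    given, an independent additive table.  ``noise_sd`` maps a site label to
    the per-call Gaussian dispersion; 0 makes the backend deterministic.

    For epistasis-free landscapes the global optimum is the per-position
    argmin, recorded as ``optimum_sequence``/``optimum_score`` at build time.
    """

    alphabet: str
    table: np.ndarray
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {SITE_BINDING: 1.0, SITE_CONTROL: 1.0}
    )
    control_offset: float = 4.0
    control_table: np.ndarray | None = None
    epistasis: list[tuple[int, int, str, str, float]] = field(default_factory=list)
    seed: int | None = None
    _pose_counter: int = field(default=0, repr=False)

    def __post_init__(self):
        self.alphabet = _canonical_alphabet(self.alphabet)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape[1] != len(self.alphabet):
            raise ValueError("table width must equal alphabet size")
        if self.control_table is not None:
            self.control_table = np.asarray(self.control_table, dtype=float)
            if self.control_table.shape != self.table.shape:
                raise ValueError("control_table shape must match table shape")
        for label, sd in self.noise_sd.items():
            if label not in SITE_LABELS:
                raise ValueError(f"unknown site label {label!r}")
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    # -- deterministic part -------------------------------------------------

    @property
    def length(self) -> int:
        return self.table.shape[0]

    def _encode(self, p: Peptide) -> np.ndarray:
        try:
            return np.fromiter(
                (self._index[r] for r in p.sequence), dtype=int, count=len(p)
            )
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} not in backend alphabet {self.alphabet}"
            ) from None

    def deterministic_mean(self, p: Peptide, site_label: str = SITE_BINDING) -> float:
        """Noise-free mean score of ``p`` at ``site_label`` (kcal/mol)."""
        if site_label not in SITE_LABELS:
            raise ValueError(f"unknown site label {site_label!r}")
        idx = self._encode(p)
        if len(p) != self.length:
            raise ValueError(
                f"peptide length {len(p)} != landscape length {self.length}"
            )
        if site_label == SITE_CONTROL and self.control_table is not None:
            total = float(self.control_table[np.arange(self.length), idx].sum())
        else:
            total = float(self.table[np.arange(self.length), idx].sum())
            if site_label == SITE_CONTROL:
                total += self.control_offset
        for i, j, res_i, res_j, term in self.epistasis:
            if p.sequence[i] == res_i and p.sequence[j] == res_j:
                total += term
        return total

    # -- stochastic part ----------------------------------------------------

    def score(
        self,
        p: Peptide,
        config: DockingConfig,
        rng: np.random.Generator,
        step_index: int = -1,
        run_index: int = -1,
    ) -> ScoreSample:
        """Draw one score sample: deterministic mean + Gaussian(0, noise_sd)."""
        mean = self.deterministic_mean(p, config.site_label)
        sd = self.noise_sd.get(config.site_label, 0.0)
        value = mean if sd == 0 else mean + sd * float(rng.standard_normal())
        self._pose_counter += 1
        return ScoreSample(
            value=value,
            site_label=config.site_label,
            pose_id=f"synthetic-{self._pose_counter}",
            step_index=step_index,
            run_index=run_index,
        )

    # -- oracle support ------------------------------------------------------

    @property
    def optimum_sequence(self) -> str:
        """Per-position argmin sequence (exact optimum when epistasis-free)."""
        if self.epistasis:
            raise ValueError("per-position optimum is undefined with epistasis terms")
        return "".join(self.alphabet[j] for j in self.table.argmin(axis=1))

    @property
    def optimum_score(self) -> float:
        if self.epistasis:
            raise ValueError("per-position optimum is undefined with epistasis terms")
        return float(self.table.min(axis=1).sum())


def flat_landscape(
    length: int,
    mean_binding: float,
    mean_control: float | None = None,
    noise_sd: float = 1.0,
    alphabet: str = CANONICAL_AA,
) -> SyntheticLandscape:
    """Sequence-independent landscape: every sequence scores ``mean_binding``.

    Handy for calibration studies of the rescoring statistics, where the
    sequence is frozen and only the score distribution matters.
    """
    canon = _canonical_alphabet(alphabet)
    table = np.full((length, len(canon)), mean_binding / length)
    offset = 0.0 if mean_control is None else mean_control - mean_binding
    return SyntheticLandscape(
        alphabet=canon,
        table=table,
        noise_sd={SITE_BINDING: noise_sd, SITE_CONTROL: noise_sd},
        control_offset=offset,
    )


def generate_landscape(
    length: int = 8,
    alphabet: str = CANONICAL_AA,
    favored_fraction: float = 0.4,
    favored_mean: float = -2.4,
    favored_sd: float = 0.05,
    background_mean: float = -1.1,
    background_sd: float = 0.25,
    noise_sd: float = 1.0,
    control_offset: float = 4.0,
    independent_control: bool = False,
    seed: int | None = None,
) -> SyntheticLandscape:
    """Draw a random additive landscape emulating a docking-score fitness surface.

    Each (position, residue) term is, with probability ``favored_fraction``, a
    draw from a tight "favored-class" mode (``favored_mean``, ``favored_sd``)
    and otherwise from a broad background mode.  The two-mode structure mirrors
    what peptide docking surfaces look like in practice — at a given site a
    class of residues (typically aromatic/hydrophobic) scores similarly well
    and clearly better than the rest.  The defaults put random sequences near
    −13 kcal/mol and the per-position optimum near −20 kcal/mol, the window
    reported for MC-refined octapeptide docking scores.

    ``independent_control=True`` draws a second, unrelated table for the
    control site instead of applying the constant ``control_offset``.
    Reproducible given ``seed``.
    """
    canon = _canonical_alphabet(alphabet)
    rng = np.random.default_rng(seed)

    def draw_table() -> np.ndarray:
        shape = (length, len(canon))
        favored = rng.random(shape) < favored_fraction
        table = rng.normal(background_mean, background_sd, shape)
        table[favored] = rng.normal(favored_mean, favored_sd, int(favored.sum()))
        return table

    table = draw_table()
    control_table = draw_table() if independent_control else None
    return SyntheticLandscape(
        alphabet=canon,
        table=table,
        noise_sd={SITE_BINDING: noise_sd, SITE_CONTROL: noise_sd},
        control_offset=control_offset,
        control_table=control_table,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Landscape (de)serialization — delimited text for reproducibility


def write_landscape(path: str | Path, landscape: SyntheticLandscape) -> None:
    """Serialize an additive landscape as TSV (site, position, residue, term).

    Header comments carry alphabet, noise levels, control offset and seed.
    Epistasis terms are an in-memory testing facility and are not serialized.
    """
    if landscape.epistasis:
        raise ValueError("landscapes with epistasis terms cannot be serialized")
    lines = [
        f"# alphabet={landscape.alphabet}",
        f"# length={landscape.length}",
        f"# noise_sd_binding={landscape.noise_sd.get(SITE_BINDING, 0.0)!r}",
        f"# noise_sd_control={landscape.noise_sd.get(SITE_CONTROL, 0.0)!r}",
        f"# control_offset={landscape.control_offset!r}",
        f"# seed={landscape.seed}",
        "site\tposition\tresidue\tterm",
    ]
    tables = [(SITE_BINDING, landscape.table)]
    if landscape.control_table is not None:
        tables.append((SITE_CONTROL, landscape.control_table))
    for site, table in tables:
        for pos, res in itertools.product(
            range(landscape.length), range(len(landscape.alphabet))
        ):
            lines.append(
                f"{site}\t{pos}\t{landscape.alphabet[res]}\t{float(table[pos, res])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_landscape(path: str | Path) -> SyntheticLandscape:
    """Inverse of :func:`write_landscape` (round-trips to full float precision)."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, str, float]] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("site\t"):
                site, pos, res, term = line.split("\t")
                rows.append((site, int(pos), res, float(term)))
    alphabet = meta["alphabet"]
    length = int(meta["length"])
    index = {a: i for i, a in enumerate(alphabet)}
    table = np.zeros((length, len(alphabet)))
    control = np.zeros((length, len(alphabet)))
    has_control = False
    for site, pos, res, term in rows:
        if site == SITE_BINDING:
            table[pos, index[res]] = term
        else:
            control[pos, index[res]] = term
            has_control = True
    seed = None if meta.get("seed", "None") == "None" else int(meta["seed"])
    return SyntheticLandscape(
        alphabet=alphabet,
        table=table,
        noise_sd={
            SITE_BINDING: float(meta["noise_sd_binding"]),
            SITE_CONTROL: float(meta["noise_sd_control"]),
        },
        control_offset=float(meta["control_offset"]),
        control_table=control if has_control else None,
        seed=seed,
    )


class ReplayBackend:
    """Replays a recorded list of scores; stands in for an external adapter.

    Used to verify the engine is indifferent to which backend is plugged in.
    Entries may be the sentinel ``"fail"`` to exercise the backend-failure
    path (mapped to proposal rejection by the engine).
    """

    def __init__(self, values, alphabet: str = CANONICAL_AA):
        self.alphabet = _canonical_alphabet(alphabet)
        self._values = list(values)
        self._cursor = 0

    def score(self, p, config, rng, step_index=-1, run_index=-1):
        if self._cursor >= len(self._values):
            raise BackendFailure("replay exhausted")
        value = self._values[self._cursor]
        self._cursor += 1
        if value == "fail":
            raise BackendFailure("recorded failure")
        return ScoreSample(
            value=float(value),
            site_label=config.site_label,
            pose_id=f"replay-{self._cursor}",
            step_index=step_index,
            run_index=run_index,
        )
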