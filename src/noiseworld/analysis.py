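"""Era-series analytics: rates, communication taxonomy, sonification.

A run's history is summarized per era by its reproduction counts with and
without the communication channel and by the position/output Pearson
correlations of the era's top reproducer.  Runs are classified by the
highest communication level attained:

* ``none`` -- the enabled channel never buys a reproduction advantage;
* ``indexical`` -- some era shows a strong one-to-one signal/position
  correlation together with a clear advantage over the muted control;
* ``symbolic`` -- a later era beats the indexical reproduction plateau
  while the correlation has collapsed and the top reproducer's output
  equation listens to the incoming signal (dialogue).

The numeric thresholds are decision-rule choices of this package (the
underlying phenomena are regime changes, not sharp lines) and are all
exposed on :class:`ClassifierConfig`.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, tree_variables

__all__ = [
    "EraSeries",
    "RunClassification",
    "ClassifierConfig",
    "uses_input_signal",
    "classify_run",
    "sonify",
    "reproduction_rate_series",
]

LABELS = ("none", "indexical", "symbolic")


@dataclass
class EraSeries:
    """Aligned per-era columns of one run's history."""

    eras: list
    births_comm: list
    births_nocomm: list
    r_x: list  # float or None (undefined: constant output)
    r_y: list

    def __post_init__(self):
        n = len(self.eras)
        for name in ("births_comm", "births_nocomm", "r_x", "r_y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length != number of eras")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "era": self.eras,
                "births_comm": self.births_comm,
                "births_nocomm": self.births_nocomm,
                "r_x": [np.nan if v is None else v for v in self.r_x],
                "r_y": [np.nan if v is None else v for v in self.r_y],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EraSeries":
        def col(name):
            return [None if pd.isna(v) else float(v) for v in df[name]]

        return cls(
            eras=[int(e) for e in df["era"]],
            births_comm=[int(b) for b in df["births_comm"]],
            births_nocomm=[int(b) for b in df["births_nocomm"]],
            r_x=col("r_x"),
            r_y=col("r_y"),
        )


@dataclass
class ClassifierConfig:
    """Thresholds of the taxonomy decision rule (all tunable)."""

    comm_advantage: float = 1.5      # comm-enabled vs muted-control ratio
    indexical_r: float = 0.9         # |r| at or above -> one-to-one signalling
    symbolic_r_max: float = 0.5      # |r| at or below -> correlation collapsed
    symbolic_rate_jump: float = 1.15  # rate vs indexical plateau
    plateau_window: int = 20         # eras of history defining the plateau


@dataclass
class RunClassification:
    label: str
    evidence: dict = field(default_factory=dict)


def uses_input_signal(genome: Genome) -> bool:
    """True iff any mutable tree references the incoming signal ``win``.

    The immutable motion equations contain no variables other than the
    heading and never count.
    """
    return any("win" in tree_variables(t.root) for t in genome.trees)


def _max_abs_r(rx, ry):
    vals = [abs(v) for v in (rx, ry) if v is not None]
    return max(vals) if vals else None


def classify_run(
    series: EraSeries,
    top_genomes: dict | None = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> RunClassification:
    """Assign the highest communication level a run's history attained.

    ``top_genomes`` maps era -> the era's top-reproducer genome; it is
    needed only to establish the dialogue condition of the symbolic label.
    Adding further eras can upgrade but never downgrade the label (all
    conditions are existential over eras).
    """
    if not series.eras:
        raise ValueError("need at least one era of data")
    top_genomes = top_genomes or {}
    n = len(series.eras)

    advantage = []
    for k in range(n):
        comm = series.births_comm[k]
        nocomm = series.births_nocomm[k]
        advantage.append(comm > 0 and comm >= cfg.comm_advantage * nocomm)

    indexical_eras = [
        series.eras[k]
        for k in range(n)
        if advantage[k]
        and (_max_abs_r(series.r_x[k], series.r_y[k]) or 0.0) >= cfg.indexical_r
    ]

    evidence = {"indexical_eras": indexical_eras}
    label = "none"
    if indexical_eras:
        label = "indexical"
        first_idx = series.eras.index(indexical_eras[0])
        for k in range(first_idx + 1, n):
            maxr = _max_abs_r(series.r_x[k], series.r_y[k])
            if maxr is None or maxr > cfg.symbolic_r_max:
                continue
            genome = top_genomes.get(series.eras[k])
            # dialogue condition: the *output* equation must listen to win
            # (a heading tree may hear the channel in the indexical regime)
            if genome is None or "win" not in tree_variables(genome.omega_tree.root):
                continue
            lo = max(0, k - cfg.plateau_window)
            window = series.births_comm[lo:k]
            if not window:
                continue
            plateau = statistics.median(window)
            if series.births_comm[k] >= cfg.symbolic_rate_jump * plateau:
                label = "symbolic"
                evidence["symbolic_era"] = series.eras[k]
                evidence["plateau"] = plateau
                evidence["rate"] = series.births_comm[k]
                evidence["max_abs_r"] = maxr
                break
    return RunClassification(label=label, evidence=evidence)


def sonify(omega_series, mode: str = "default") -> pd.DataFrame:
    """Map an output-signal series to audio frequencies.

    ``default``: freq = 14 (omega + 25); ``fig2``: freq = 140 (omega + 25)
    - 3150.  Either way frequencies are clamped to [210, 490] Hz and each
    sample sounds for 0.05 s.
    """
    omega = np.asarray(omega_series, dtype=float)
    if mode == "default":
        freq = 14.0 * (omega + 25.0)
    elif mode == "fig2":
        freq = 140.0 * (omega + 25.0) - 3150.0
    else:
        raise ValueError(f"unknown sonification mode {mode!r}")
    freq = np.clip(freq, 210.0, 490.0)
    return pd.DataFrame(
        {"t": np.arange(len(omega)), "freq_hz": freq, "duration_s": 0.05}
    )


def reproduction_rate_series(birth_log, island=None) -> pd.DataFrame:
    """Per-era reproduction counts from a run's birth log.

    ``birth_log`` rows are ``(era, island, births)``.  Counts are summed
    over islands unless a single ``island`` is selected.  Eras missing
    from a contiguous range appear with a NaN count (gap flag).
    """
    df = pd.DataFrame(birth_log, columns=["era", "island", "births"])
    if island is not None:
        df = df[df["island"] == island]
    if df.empty:
        return pd.DataFrame({"era": [], "births": []})
    per_era = df.groupby("era")["births"].sum()
    full = range(int(per_era.index.min()), int(per_era.index.max()) + 1)
    per_era = per_era.reindex(full)
    return per_era.rename_axis("era").reset_index()
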