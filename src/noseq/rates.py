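"""Per-position base composition and conversion rates of an aligned read set.

Because only full-window, perfectly scored, anchored reads enter the set,
coverage is constant across positions and every per-position count vector
sums to the number of aligned reads.  Rates are plain fractions of aligned
reads: the A rate (and complementary G rate) at reference A positions
tracks A-to-I conversion, the T rate at reference C positions tracks
C-to-U conversion.  m6A resists deamination, so a methylated site keeps an
elevated A rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignedReadSet, BASES, encode
from .exceptions import EmptyInputError, ValidationError
from .io import ReferenceAmplicon

__all__ = ["RateTable", "UniformitySummary", "tabulate", "deamination_uniformity"]


@dataclass
class RateTable:
    """Per-position base counts and derived conversion rates.

    ``counts`` is (L, 4) over A/C/G/T; rates are indexed by 1-based position
    and defined only at the relevant reference positions (A positions for
    a_rate/g_rate, C positions for t_rate).  Denominators are always the
    total aligned-read count, so bases outside {A, G} at an A position
    (sequencing error) reduce a_rate + g_rate below 1 rather than being
    dropped.
    """

    reference: ReferenceAmplicon
    counts: np.ndarray
    n_reads: int

    @property
    def length(self) -> int:
        return len(self.reference)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def _rate(self, positions: tuple[int, ...], base: str) -> pd.Series:
        col = BASES.index(base)
        idx = np.array(positions, dtype=int) - 1
        return pd.Series(
            self.counts[idx, col] / self.n_reads, index=list(positions), name=f"{base.lower()}_rate"
        )

    @property
    def a_rate(self) -> pd.Series:
        """Fraction of reads showing A at each reference A position."""
        return self._rate(self.reference.a_positions, "A")

    @property
    def g_rate(self) -> pd.Series:
        """Fraction of reads showing G at each reference A position (A-to-I)."""
        return self._rate(self.reference.a_positions, "G")

    @property
    def t_rate(self) -> pd.Series:
        """Fraction of reads showing T at each reference C position (C-to-U)."""
        return self._rate(self.reference.c_positions, "T")

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: position, ref_base, counts, rates (NaN where undefined)."""
        length = self.length
        positions = np.arange(1, length + 1)
        df = pd.DataFrame(
            {
                "position": positions,
                "ref_base": list(self.reference.sequence),
                "n_A": self.counts[:, 0],
                "n_C": self.counts[:, 1],
                "n_G": self.counts[:, 2],
                "n_T": self.counts[:, 3],
            }
        )
        df["a_rate"] = np.where(
            df["ref_base"] == "A", df["n_A"] / self.n_reads, np.nan
        )
        df["g_rate"] = np.where(
            df["ref_base"] == "A", df["n_G"] / self.n_reads, np.nan
        )
        df["t_rate"] = np.where(
            df["ref_base"] == "C", df["n_T"] / self.n_reads, np.nan
        )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def tabulate(aligned: AlignedReadSet) -> RateTable:
    """Sum A/C/G/T counts per position over all aligned reads."""
    if not aligned.reads:
        raise EmptyInputError("no aligned reads to tabulate")
    length = len(aligned.reference)
    block = np.empty((len(aligned.reads), length), dtype=np.uint8)
    for row, read in enumerate(aligned.reads):
        block[row] = encode(read.aligned_bases)
    counts = np.zeros((length, 4), dtype=np.int64)
    for code in range(4):
        counts[:, code] = (block == code).sum(axis=0)
    return RateTable(
        reference=aligned.reference, counts=counts, n_reads=len(aligned.reads)
    )


@dataclass
class UniformitySummary:
    """Dispersion of conversion rates across non-candidate positions.

    Used to check that deamination is uniform along the amplicon (no
    primer-proximal bias): the coefficient of variation of the G rate over
    A positions and of the T rate over C positions.
    """

    mean_g_rate: float
    sd_g_rate: float
    cv_g_rate: float
    n_a_positions: int
    mean_t_rate: float
    sd_t_rate: float
    cv_t_rate: float
    n_c_positions: int


def deamination_uniformity(
    rate_table: RateTable, exclude: tuple[int, ...] = ()
) -> UniformitySummary:
    """Mean/SD/CV of conversion rates, excluding candidate positions.

    ``exclude`` normally lists the suspected m6A positions so their
    protected signal does not inflate the dispersion estimate.  Requires at
    least 3 assessable A positions after exclusion.
    """
    excluded = set(exclude)
    g = rate_table.g_rate.drop(labels=excluded, errors="ignore")
    t = rate_table.t_rate.drop(labels=excluded, errors="ignore")
    if len(g) < 3:
        raise ValidationError(
            f"only {len(g)} A positions left after exclusion; need >= 3"
        )
    def _cv(series: pd.Series) -> tuple[float, float, float]:
        mean = float(series.mean())
        sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
        return mean, sd, (sd / mean if mean > 0 else np.nan)

    mg, sg, cg = _cv(g)
    mt, st, ct = _cv(t) if len(t) else (np.nan, np.nan, np.nan)
    return UniformitySummary(
        mean_g_rate=mg, sd_g_rate=sg, cv_g_rate=cg, n_a_positions=len(g),
        mean_t_rate=mt, sd_t_rate=st, cv_t_rate=ct, n_c_positions=len(t),
    )
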