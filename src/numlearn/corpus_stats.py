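"""Spoken-frequency statistics of number words.

Ships the per-million spoken frequencies of the number words one-seven in
English (COCA) and Spanish (Corpus del Espanol), and provides the
distributional analyses built on them: relative frequencies, the
cross-language correlation, and the inverse power fit f(n) = a * n^(-b) used
to extrapolate how often sets of 8-20 objects are talked about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrequencyTable",
    "PowerFit",
    "load_frequency_tables",
    "english_table",
    "spanish_table",
    "relative_frequencies",
    "crosslang_correlation",
    "fit_inverse_power",
    "set_size_weights",
]

_DATA_FILE = "number_word_frequencies.tsv"


@dataclass(frozen=True)
class FrequencyTable:
    """Spoken frequencies (tokens per million words) of numbers by language."""

    language: str
    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("frequency table must be non-empty")
        if any(f <= 0 for _, f in self.entries):
            raise ValueError("frequencies must be strictly positive")

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.entries], dtype=float)

    def __getitem__(self, number: int) -> float:
        for n, f in self.entries:
            if n == number:
                return f
        raise KeyError(number)


def _data_text() -> str:
    return (resources.files("numlearn.data") / _DATA_FILE).read_text()


def load_frequency_tables() -> tuple[FrequencyTable, FrequencyTable]:
    """The embedded English and Spanish number-word frequency tables."""
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text()), sep="\t")
    eng = FrequencyTable(
        "English",
        tuple(zip(df["number"].astype(int), df["english_per_million"].astype(float))),
    )
    spa = FrequencyTable(
        "Spanish",
        tuple(zip(df["number"].astype(int), df["spanish_per_million"].astype(float))),
    )
    return eng, spa


def english_table() -> FrequencyTable:
    return load_frequency_tables()[0]


def spanish_table() -> FrequencyTable:
    return load_frequency_tables()[1]


def relative_frequencies(table: FrequencyTable) -> dict[int, float]:
    """Each number's share of the table's total; proportions sum to 1."""
    total = float(table.frequencies.sum())
    if total <= 0:
        raise ValueError("total frequency must be positive")
    return {n: f / total for n, f in table.entries}


def crosslang_correlation(
    t1: FrequencyTable, t2: FrequencyTable, relative: bool = True
) -> float:
    """Pearson r between the two languages' number-word frequencies.

    Computed on relative frequencies by default; because Pearson r is
    invariant to rescaling either vector, raw per-million counts give the
    same value.
    """
    if t1.numbers != t2.numbers:
        raise ValueError("tables must cover the same numbers")
    x, y = t1.frequencies, t2.frequencies
    if relative:
        x, y = x / x.sum(), y / y.sum()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant frequency vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PowerFit:
    """Inverse power law f(n) = a * n^(-b) fitted to a frequency table."""

    a: float
    b: float
    fit_domain: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale coefficient a must be positive")

    def predict(self, n: int | np.ndarray) -> float | np.ndarray:
        out = self.a * np.asarray(n, dtype=float) ** (-self.b)
        return float(out) if out.ndim == 0 else out


def fit_inverse_power(table: FrequencyTable) -> PowerFit:
    """Ordinary least squares in log-log space: log f = log a - b log n."""
    if len(table.entries) < 3:
        raise ValueError("need at least 3 entries to fit a power law")
    n = np.array(table.numbers, dtype=float)
    f = table.frequencies
    slope, intercept = np.polyfit(np.log(n), np.log(f), 1)
    return PowerFit(a=float(math.exp(intercept)), b=float(-slope), fit_domain=table.numbers)


def set_size_weights(
    max_size: int = 20, table: FrequencyTable | None = None
) -> dict[int, float]:
    """Environmental relevance weights for set sizes 1..max_size.

    Sizes covered by the table use its observed frequencies; larger sizes
    extend the tail with the fitted power-law exponent anchored at the last
    observed point, w(n) = f(n_max) * (n / n_max)^(-b), which keeps the
    combined weight vector continuous and strictly decreasing.  (Anchoring
    matters because the observed tail value sits below the fitted curve, so
    raw fit predictions would jump back up at the seam.)
    """
    if table is None:
        table = english_table()
    n_obs = max(table.numbers)
    weights = {n: float(f) for n, f in table.entries if n <= max_size}
    if max_size > n_obs:
        b = fit_inverse_power(table).b
        anchor = table[n_obs]
        for n in range(n_obs + 1, max_size + 1):
            weights[n] = float(anchor * (n / n_obs) ** (-b))
    return weights


def summary_frame() -> pd.DataFrame:
    """One row per number: raw and relative frequencies in both languages."""
    eng, spa = load_frequency_tables()
    rel_e, rel_s = relative_frequencies(eng), relative_frequencies(spa)
    return pd.DataFrame(
        {
            "number": eng.numbers,
            "english_per_million": eng.frequencies,
            "spanish_per_million": spa.frequencies,
            "english_relative": [rel_e[n] for n in eng.numbers],
            "spanish_relative": [rel_s[n] for n in spa.numbers],
        }
    )
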