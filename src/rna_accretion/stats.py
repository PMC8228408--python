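"""Length-versus-age series and their correlation statistics.

For each homologous substructure we take its mean coded length across taxa
(absences excluded) and its relative node-distance age, then ask whether
length decreases with age. Association is measured three ways: ordinary
least squares of mean length on age, Pearson's r with a two-sided t-test,
and Spearman's rho (robust to outliers; exact two-tailed permutation p-value
for small n). Marginal normality of the lengths is screened with a
Kolmogorov-Smirnov test against a normal with plug-in mean/sd, plus a
Lilliefors-corrected p-value since the plug-in KS p is conservative.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .structure import CharacterMatrix, decode_state
from .trees import SubstructureAge

__all__ = [
    "AccretionSeries",
    "CorrelationResult",
    "mean_lengths",
    "build_series",
    "correlate",
    "spearman_exact_p",
]

#: Largest n for which the Spearman permutation p-value is exact (n! perms).
EXACT_SPEARMAN_N = 9


@dataclass
class AccretionSeries:
    """Per-substructure records of age, mean length, and accretion rank.

    ``x`` is the accretion rank: the number of substructures with age <= this
    one, so ties in nd share x and x counts the parts the growing molecule
    has accumulated by that time.
    """

    data: pd.DataFrame  # columns: label, cls, nd, mean_length, x

    def __post_init__(self) -> None:
        required = {"label", "cls", "nd", "mean_length", "x"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"series missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def nd(self) -> np.ndarray:
        return self.data["nd"].to_numpy(float)

    @property
    def mean_length(self) -> np.ndarray:
        return self.data["mean_length"].to_numpy(float)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(int)

    def filter_class(self, cls: str) -> "AccretionSeries":
        sub = self.data[self.data["cls"] == cls].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records of class {cls!r}")
        return AccretionSeries(sub)

    def to_tsv(self) -> str:
        return self.data.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "AccretionSeries":
        """Read ``label class nd mean_length`` TSV; x recomputed from nd.

        Lets externally curated chronologies bypass the upstream modules.
        """
        df = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
        if "class" in df.columns:
            df = df.rename(columns={"class": "cls"})
        df = df.sort_values("nd", kind="stable").reset_index(drop=True)
        df["x"] = _accretion_ranks(df["nd"].to_numpy(float))
        return cls(df)


@dataclass
class CorrelationResult:
    """OLS + correlation + normality summary for one length-vs-age series."""

    slope: float
    intercept: float
    R2: float
    r: float
    p_r: float
    rho: float
    p_rho: float
    df: int
    D: float
    p_D: float
    p_D_lilliefors: float
    n: int

    def stars(self, p: float) -> str:
        if p < 0.001:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def mean_lengths(matrix: CharacterMatrix) -> dict[str, float]:
    """Mean decoded length per character, absences (state '0') excluded.

    Characters absent in every taxon are dropped with a warning.
    """
    out: dict[str, float] = {}
    for ci, ch in enumerate(matrix.characters):
        vals = [
            decode_state(row[ci]) for row in matrix.states if row[ci] != "0"
        ]
        if not vals:
            warnings.warn(
                f"character {ch.label!r} absent in all taxa; dropped",
                stacklevel=2,
            )
            continue
        out[ch.label] = float(np.mean(vals))
    return out


def _accretion_ranks(nd: np.ndarray) -> np.ndarray:
    """x_i = number of entries with nd <= nd_i (ties share the count)."""
    return np.array([(nd <= v).sum() for v in nd], dtype=int)


def build_series(
    means: Mapping[str, float],
    ages: Sequence[SubstructureAge],
    classes: Mapping[str, str] | None = None,
    class_filter: str | None = None,
) -> AccretionSeries:
    """Join mean lengths with ages into an accretion series sorted by age.

    ``classes`` maps labels to helical/unpaired (e.g.,
    ``CharacterMatrix.classes()``); ``class_filter`` keeps one class. Every
    mean-length label must have an age and vice versa.
    """
    age_map = {a.label: a.nd for a in ages}
    cls_map = dict(classes or {})
    labels = sorted(means)
    if class_filter is not None:
        labels = [l for l in labels if cls_map.get(l) == class_filter]
        if not labels:
            raise ValueError(f"no substructures of class {class_filter!r}")
    no_age = [l for l in labels if l not in age_map]
    if no_age:
        raise ValueError(f"labels with mean length but no age: {no_age}")
    no_mean = [
        l for l in age_map
        if l not in means
        and (class_filter is None or cls_map.get(l) == class_filter)
        and l in cls_map
    ]
    if no_mean:
        raise ValueError(f"labels with age but no mean length: {no_mean}")
    df = pd.DataFrame(
        {
            "label": labels,
            "cls": [cls_map.get(l, "unknown") for l in labels],
            "nd": [age_map[l] for l in labels],
            "mean_length": [means[l] for l in labels],
        }
    ).sort_values(["nd", "label"], kind="stable").reset_index(drop=True)
    df["x"] = _accretion_ranks(df["nd"].to_numpy(float))
    return AccretionSeries(df)


def spearman_exact_p(xr: np.ndarray, yr: np.ndarray) -> float:
    """Exact two-tailed permutation p for Spearman's rho (small n).

    Enumerates all n! orderings of the y ranks; p is the fraction with
    |rho| >= |rho observed| (within numerical tolerance). Average ranks are
    used for ties, so the null distribution conditions on the tie pattern.
    """
    n = len(xr)
    rho_obs = _pearson(xr, yr)
    perms = np.array(list(itertools.permutations(range(n))))
    ys = yr[perms]
    xs = xr[None, :]
    xc = xs - xs.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / math.sqrt((a**2).sum() * (b**2).sum()))


def correlate(series: AccretionSeries) -> CorrelationResult:
    """Correlation/normality battery for mean length against age.

    OLS regresses mean length on nd (ages in [0, 1], so the slope is in
    nucleotides or base pairs per unit relative time). Spearman's p is an
    exact two-tailed permutation value for n <= 9 and the t approximation
    otherwise. The KS test checks the lengths against a normal with sample
    mean and sd; the Lilliefors p corrects for that estimation.
    """
    n = len(series)
    if n < 3:
        raise ValueError(f"need >= 3 records, got {n}")
    x = series.nd
    y = series.mean_length
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in age or length: correlation undefined")

    ols = sps.linregress(x, y)
    r, p_r = sps.pearsonr(x, y)

    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _pearson(xr, yr)
    if n <= EXACT_SPEARMAN_N:
        p_rho = spearman_exact_p(xr, yr)
    else:
        p_rho = float(sps.spearmanr(x, y).pvalue)

    mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
    D, p_D = sps.kstest(y, "norm", args=(mu, sd))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n table interpolation
        _, p_lf = lilliefors(y, dist="norm")

    return CorrelationResult(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        R2=float(r) ** 2,
        r=float(r),
        p_r=float(p_r),
        rho=float(rho),
        p_rho=p_rho,
        df=n - 2,
        D=float(D),
        p_D=float(p_D),
        p_D_lilliefors=float(p_lf),
        n=n,
    )
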