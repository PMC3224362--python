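"""Letter-preference statistics on the letters × compartments count table.

The central object is the contingency table N(sl, cp) counting how often each
structural letter sl occurs in each compartment cp ∈ {interface, surface,
core} (residues in the *undefined* compartment are excluded).  On it we
compute:

* the non-symmetrized Kullback–Leibler divergence of each letter's
  compartment distribution from its secondary-structure class distribution,
  KLd(sl) = Σ_cp p_sl,cp ln(p_sl,cp / p_ss,cp); the quantity 2·N_sl·KLd(sl)
  is compared to the 0.95 quantile of χ² with 2 degrees of freedom (5.99);
* Z-scores Z_cp1/cp2(sl) = (N_obs − N_exp)/√N_exp assessing the preferred
  compartment of a letter, with N_exp = (class total in cp1) × f_cp2(sl) and
  the validity rule N_exp > 5, thresholded after Bonferroni correction;
* correspondence analysis of the table (SVD of standardized residuals) and
  PCA of the 27×4 descriptor table;
* the percentage of a secondary-structure class affected by preferential
  distribution, Σ_sl max(Obs−Exp, 0) / Σ_sl Obs per compartment;
* amino-acid composition per (letter, compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CLASS_LETTERS, SS_CLASS

__all__ = [
    "COMPARTMENTS",
    "CHI2_DF",
    "CHI2_CRITICAL_95",
    "kld_quantities",
    "CountTable",
    "count_letters",
    "KldEntry",
    "kld",
    "kld_table",
    "ZscoreEntry",
    "zscore",
    "zscore_table",
    "bonferroni_threshold",
    "OrdinationResult",
    "correspondence_analysis",
    "pca_descriptors",
    "preferential_pct",
    "aa_composition",
]

COMPARTMENTS = ("interface", "surface", "core")
#: degrees of freedom of the KLd quantity: 3 compartments − 1
CHI2_DF = 2
#: χ²(df=2) 0.95 quantile — the KLd significance bar
CHI2_CRITICAL_95 = float(sps.chi2.ppf(0.95, CHI2_DF))


def kld_quantities(counts, class_freq) -> np.ndarray:
    """KLd quantities 2·N_sl·KLd for one or many count vectors.

    ``counts`` is (3,) or (reps, 3); ``class_freq`` the reference class
    distribution.  Zero observed cells contribute 0 (0·ln(0/q) := 0).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    q = np.asarray(class_freq, dtype=float)
    n = counts.sum(axis=1)
    if np.any(n <= 0):
        raise ValueError("count vectors must have positive totals")
    if np.any((q <= 0) & (counts > 0).any(axis=0)):
        raise ValueError("class frequency zero where counts have mass")
    p = counts / n[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return 2.0 * n * terms.sum(axis=1)


@dataclass
class CountTable:
    """Letters × compartments occurrence matrix with class bookkeeping."""

    counts: pd.DataFrame                       # index: letters, columns: compartments
    classes: dict[str, str] = field(default_factory=lambda: dict(SS_CLASS))

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(COMPARTMENTS)).fillna(0)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(int)

    @classmethod
    def from_dict(cls, d: dict[str, dict[str, int]], classes=None) -> "CountTable":
        frame = pd.DataFrame.from_dict(d, orient="index")
        return cls(frame, classes=classes or dict(SS_CLASS))

    def letters(self) -> list[str]:
        return list(self.counts.index)

    def letter_total(self, letter: str) -> int:
        return int(self.counts.loc[letter].sum())

    def class_letters(self, letter_or_class: str) -> list[str]:
        cls = self.classes.get(letter_or_class, letter_or_class)
        return [l for l in self.counts.index if self.classes.get(l) == cls]

    def class_counts(self, letter_or_class: str) -> pd.Series:
        """Per-compartment totals of the letter's secondary-structure class."""
        return self.counts.loc[self.class_letters(letter_or_class)].sum(axis=0)


def count_letters(sequences, accessibility_records, class_filter: str | None = None,
                  classes: dict[str, str] | None = None) -> CountTable:
    """Tally residues carrying both a structural letter and a compartment.

    ``sequences`` are :class:`~sashape.encoder.StructuralSequence` objects,
    ``accessibility_records`` :class:`~sashape.sasa.AccessibilityRecord`
    lists; residues in the undefined compartment contribute nothing.
    """
    classes = classes or dict(SS_CLASS)
    compartment_of = {}
    for rec in accessibility_records:
        if rec.compartment in COMPARTMENTS:
            compartment_of[rec.residue] = rec.compartment
    counts: dict[str, dict[str, int]] = {}
    n = 0
    for seq in sequences:
        for key, letter in seq.residue_letter_map.items():
            cp = compartment_of.get(key)
            if cp is None:
                continue
            if class_filter and classes.get(letter) != class_filter:
                continue
            counts.setdefault(letter, {c: 0 for c in COMPARTMENTS})[cp] += 1
            n += 1
    if n == 0:
        raise ValueError("no residue carries both a letter and a compartment")
    return CountTable(pd.DataFrame.from_dict(counts, orient="index"), classes=classes)


@dataclass
class KldEntry:
    letter: str
    kld: float                      # nats
    n_sl: int
    quantity: float                 # 2 · N_sl · KLd
    critical: float                 # χ²(df=2) 0.95 quantile
    significant: bool


def kld(table: CountTable, letter: str, alpha: float = 0.05) -> KldEntry:
    """Kullback–Leibler divergence of one letter's compartment distribution
    from its class distribution, with the χ² significance flag."""
    obs = table.counts.loc[letter].to_numpy(dtype=float)
    n_sl = obs.sum()
    if n_sl <= 0:
        raise ValueError(f"letter {letter!r} has no occurrences")
    class_counts = table.class_counts(letter).to_numpy(dtype=float)
    q = class_counts / class_counts.sum()
    try:
        quantity = float(kld_quantities(obs, q)[0])
    except ValueError:
        raise ValueError(
            f"class frequency zero where letter {letter!r} has mass") from None
    value = quantity / (2.0 * n_sl)
    critical = float(sps.chi2.ppf(1.0 - alpha, CHI2_DF))
    return KldEntry(letter, value, int(n_sl), quantity, critical,
                    quantity > critical)


def kld_table(table: CountTable, alpha: float = 0.05) -> pd.DataFrame:
    rows = [kld(table, l, alpha=alpha) for l in table.letters()
            if table.letter_total(l) > 0]
    return pd.DataFrame([vars(r) for r in rows]).set_index("letter")


@dataclass
class ZscoreEntry:
    letter: str
    cp1: str
    cp2: str
    n_obs: float
    n_exp: float
    z: float
    meaningful: bool                # N_exp > 5
    threshold: float                # Bonferroni-corrected |Z| significance bar
    significant: bool


def bonferroni_threshold(alpha: float = 0.05, m: int = 1,
                         sided: str = "two") -> float:
    """Standard-normal quantile after Bonferroni correction of m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if sided == "two":
        return float(sps.norm.ppf(1.0 - alpha / (2.0 * m)))
    if sided == "one":
        return float(sps.norm.ppf(1.0 - alpha / m))
    raise ValueError("sided must be 'one' or 'two'")


def zscore(table: CountTable, letter: str, cp1: str, cp2: str,
           alpha: float = 0.05, sided: str = "two",
           m: int | None = None) -> ZscoreEntry:
    """Preference of ``letter`` for compartment ``cp1`` over ``cp2``.

    The expected count is the class total in cp1 times the letter's relative
    frequency within its class in cp2; the default Bonferroni family is
    (letters in the class) × 3 ordered compartment pairs.
    """
    class_counts = table.class_counts(letter)
    if class_counts[cp1] <= 0 or class_counts[cp2] <= 0:
        raise ValueError("class totals must be positive in both compartments")
    n_obs = float(table.counts.loc[letter, cp1])
    f_cp2 = float(table.counts.loc[letter, cp2]) / float(class_counts[cp2])
    n_exp = float(class_counts[cp1]) * f_cp2
    if n_exp == 0:
        return ZscoreEntry(letter, cp1, cp2, n_obs, 0.0, float("nan"),
                           False, float("nan"), False)
    z = (n_obs - n_exp) / np.sqrt(n_exp)
    if m is None:
        m = len(table.class_letters(letter)) * 3
    t = bonferroni_threshold(alpha=alpha, m=m, sided=sided)
    meaningful = n_exp > 5
    return ZscoreEntry(letter, cp1, cp2, n_obs, n_exp, float(z),
                       meaningful, t, bool(meaningful and abs(z) > t))


_Z_PAIRS = (("interface", "surface"), ("interface", "core"), ("surface", "core"))


def zscore_table(table: CountTable, alpha: float = 0.05,
                 sided: str = "two") -> pd.DataFrame:
    rows = []
    for letter in table.letters():
        for cp1, cp2 in _Z_PAIRS:
            try:
                rows.append(vars(zscore(table, letter, cp1, cp2,
                                        alpha=alpha, sided=sided)))
            except ValueError:
                continue
    return pd.DataFrame(rows)


@dataclass
class OrdinationResult:
    method: str
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    values: np.ndarray              # inertias or eigenvalues per axis
    explained: np.ndarray           # fraction per axis (sums to 1 when total > 0)
    total: float
    degenerate: bool = False


def correspondence_analysis(table: CountTable | pd.DataFrame) -> OrdinationResult:
    """Simple correspondence analysis of the letters × compartments table.

    SVD of the standardized-residual matrix S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}
    with P the correspondence matrix and r, c its margins; principal
    coordinates are returned for rows (letters) and columns (compartments).
    """
    frame = table.counts if isinstance(table, CountTable) else pd.DataFrame(table)
    n = frame.to_numpy(dtype=float)
    if n.sum() <= 0:
        raise ValueError("empty table")
    p = n / n.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("all row and column margins must be positive")
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    max_axes = min(len(r), len(c)) - 1
    sv = sv[:max_axes]
    u, vt = u[:, :max_axes], vt[:max_axes]
    inertia = sv ** 2
    total = float(inertia.sum())
    keep = sv > 1e-12
    degenerate = int(keep.sum()) < max_axes
    explained = inertia / total if total > 0 else np.zeros_like(inertia)
    row = (u * sv) / np.sqrt(r)[:, None]
    col = (vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i+1}" for i in range(len(sv))]
    return OrdinationResult(
        "correspondence_analysis",
        pd.DataFrame(row, index=frame.index, columns=axes),
        pd.DataFrame(col, index=frame.columns, columns=axes),
        inertia, explained, total, degenerate)


def pca_descriptors(descriptors, letters=None,
                    standardize: bool = True) -> OrdinationResult:
    """PCA of the per-letter descriptor table (27 × 4 by default).

    Columns are standardized by default (the four descriptors mix distances
    with a signed projection of different spreads); ``standardize=False``
    decomposes the raw covariance instead.
    """
    x = np.asarray(descriptors, dtype=float)
    if x.ndim != 2 or not np.all(np.isfinite(x)):
        raise ValueError("descriptor table must be a finite 2-D array")
    mu = x.mean(axis=0)
    xc = x - mu
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column cannot be standardized")
        xc = xc / sd
    cov = np.cov(xc, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    total = float(vals.sum())
    explained = vals / total if total > 0 else np.zeros_like(vals)
    scores = xc @ vecs
    axes = [f"PC{i+1}" for i in range(len(vals))]
    idx = letters if letters is not None else range(len(x))
    cols = ["d1", "d2", "d3", "p4"][:x.shape[1]] if x.shape[1] <= 4 else range(x.shape[1])
    return OrdinationResult(
        "pca",
        pd.DataFrame(scores, index=idx, columns=axes),
        pd.DataFrame(vecs, index=cols, columns=axes),
        vals, explained, total)


def preferential_pct(table: CountTable, ss_class: str, compartment: str) -> float:
    """Percent of a class's occurrences in a compartment that exceed the
    expectation under class-proportional distribution.

    Exp(sl, cp) = N_total(sl) × class total in cp / class total overall;
    the statistic is Σ_sl max(Obs − Exp, 0) / Σ_sl Obs × 100 over the class's
    letters in that compartment.
    """
    letters = table.class_letters(ss_class)
    if not letters:
        raise ValueError(f"no letters of class {ss_class!r} in table")
    class_cp = float(table.counts.loc[letters, compartment].sum())
    class_all = float(table.counts.loc[letters].to_numpy().sum())
    if class_all <= 0 or class_cp <= 0:
        raise ValueError("empty class or compartment")
    excess, observed = 0.0, 0.0
    for l in letters:
        obs = float(table.counts.loc[l, compartment])
        exp = table.letter_total(l) * class_cp / class_all
        excess += max(obs - exp, 0.0)
        observed += obs
    return 100.0 * excess / observed


def aa_composition(sequences, accessibility_records) -> pd.DataFrame:
    """Amino-acid proportions per (letter, compartment).

    Rows are (letter, compartment) pairs, columns the 20 amino acids; each
    row sums to 1 over the residues carrying that letter in that compartment.
    """
    compartment_of, aa_of = {}, {}
    for rec in accessibility_records:
        if rec.compartment in COMPARTMENTS:
            compartment_of[rec.residue] = rec.compartment
            aa_of[rec.residue] = rec.aa
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for seq in sequences:
        aa_chain = dict(zip(seq.chain.keys, seq.chain.aa))
        for key, letter in seq.residue_letter_map.items():
            cp = compartment_of.get(key)
            if cp is None:
                continue
            aa = aa_of.get(key) or aa_chain.get(key, "X")
            tallies.setdefault((letter, cp), {})[aa] = \
                tallies.get((letter, cp), {}).get(aa, 0) + 1
    if not tallies:
        raise ValueError("no residue carries both a letter and a compartment")
    frame = pd.DataFrame.from_dict(tallies, orient="index").fillna(0.0)
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["letter", "compartment"])
    return frame.div(frame.sum(axis=1), axis=0)
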