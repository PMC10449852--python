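"""Seeded generators for Km-[S] tables and landscape fixtures.

The table generator emulates the statistical structure of the reference
Km vs in-vivo concentration dataset: per-category log10(Km/[S]) ratios that
are Gaussian with category-specific centers and spreads, substrate
occurrence counts spanning the <=50 / 51-299 / >=300 classes, and in-vivo
concentrations spread over roughly six decades.  Category sizes and centers
default to the reference dataset's (980 major-metabolite entries centered
at -0.18 with SD 1.3; 410 cofactor entries at -0.43 over 5 substrates; 313
ATP entries at -1.64).

Everything is deterministic for a fixed seed: one ``numpy.random.default_rng``
stream per generator call, consumed in a documented order (per category:
ratios first, then concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import AssayCondition, ThermoLandscape

__all__ = [
    "CategorySpec",
    "KmTableSpec",
    "generate_km_dataset",
    "generate_landscapes",
    "DEFAULT_TABLE_SPEC",
]

_ORGANISMS = ("Escherichia coli", "Saccharomyces cerevisiae", "Mus musculus")


@dataclass(frozen=True)
class CategorySpec:
    """One occurrence class of the synthetic table."""

    label: str
    n_entries: int
    ratio_mu: float  # center of log10(Km/[S])
    ratio_sigma: float  # spread of log10(Km/[S]), >= 0
    n_substrates: int
    max_per_substrate: int | None = None  # occurrence-class upper bound
    min_per_substrate: int = 1

    def __post_init__(self) -> None:
        if self.n_entries < 0 or self.n_substrates <= 0:
            raise ValueError("n_entries >= 0 and n_substrates >= 1 required")
        if self.ratio_sigma < 0:
            raise ValueError("ratio_sigma must be >= 0")

    def occurrence_counts(self) -> list[int]:
        """Entries per substrate: as even as possible, thresholds respected."""
        n, k = self.n_entries, self.n_substrates
        base, extra = divmod(n, k)
        counts = [base + (1 if i < extra else 0) for i in range(k)]
        if self.max_per_substrate is not None and counts and counts[0] > self.max_per_substrate:
            raise ValueError(
                f"category {self.label!r}: {n} entries over {k} substrates needs "
                f"{counts[0]} per substrate, above the class bound {self.max_per_substrate}"
            )
        if counts and counts[-1] < self.min_per_substrate:
            raise ValueError(
                f"category {self.label!r}: too many substrates for {n} entries "
                f"(class requires >= {self.min_per_substrate} each)"
            )
        return counts


@dataclass(frozen=True)
class KmTableSpec:
    """Full specification of a synthetic Km-[S] table."""

    categories: tuple[CategorySpec, ...]
    logS_range: tuple[float, float] = (-2.0, 4.0)  # log10 uM

    def __post_init__(self) -> None:
        if self.logS_range[0] >= self.logS_range[1]:
            raise ValueError("logS_range must satisfy min < max")


#: Reference conditions: category sizes and log-ratio centers of the
#: wild-type Km vs in-vivo concentration dataset.
DEFAULT_TABLE_SPEC = KmTableSpec(
    categories=(
        CategorySpec("major_metabolite", 980, -0.18, 1.3, 40, max_per_substrate=50),
        CategorySpec("cofactor", 410, -0.43, 1.1, 5, min_per_substrate=51, max_per_substrate=299),
        CategorySpec("ATP", 313, -1.64, 0.9, 1, min_per_substrate=300),
    ),
)

_CATEGORY_SUBSTRATE_STEM = {
    "major_metabolite": "metabolite",
    "cofactor": "cofactor",
    "ATP": "ATP_like",
}


def generate_km_dataset(
    spec: KmTableSpec | None = None,
    seed: int = 0,
    path=None,
) -> pd.DataFrame:
    """Generate a synthetic Km-[S] table (and optionally write it as CSV).

    Per entry, the in-vivo concentration [S] is drawn log-uniformly over
    ``spec.logS_range`` and Km = [S] * 10^r with r ~ N(ratio_mu,
    ratio_sigma) of the entry's category.  Columns: substrate, Km, S,
    organism, category (concentrations in uM), directly loadable by
    :func:`enzact.dataset.load_km_dataset` with ``units={"Km": "uM",
    "S": "uM"}``.

    Deterministic for a fixed seed; when ``path`` is given the CSV is
    written with a fixed float format so repeated runs are byte-identical.
    """
    if spec is None:
        spec = DEFAULT_TABLE_SPEC
    rng = np.random.default_rng(seed)
    rows = []
    for cat in spec.categories:
        counts = cat.occurrence_counts()
        ratios = rng.normal(cat.ratio_mu, cat.ratio_sigma, size=cat.n_entries)
        logS = rng.uniform(*spec.logS_range, size=cat.n_entries)
        stem = _CATEGORY_SUBSTRATE_STEM.get(cat.label, cat.label)
        j = 0
        for i_sub, c in enumerate(counts):
            name = f"{stem}_{i_sub:03d}" if len(counts) > 1 else stem
            for _ in range(c):
                s_val = 10.0 ** logS[j]
                rows.append({
                    "substrate": name,
                    "Km": s_val * 10.0 ** ratios[j],
                    "S": s_val,
                    "organism": _ORGANISMS[j % len(_ORGANISMS)],
                    "category": cat.label,
                })
                j += 1
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.10g")
    return df


def generate_landscapes(
    n: int,
    seed: int = 0,
    dG1_range: tuple[float, float] = (-60.0, 20.0),
    dGT_range: tuple[float, float] = (-80.0, 0.0),
    alpha_range: tuple[float, float] = (0.05, 0.95),
    logk_range: tuple[float, float] = (-2.0, 2.0),
    S_range_log10: tuple[float, float] = (-2.0, 3.0),
    complementary_alphas: bool = False,
) -> list[tuple[ThermoLandscape, AssayCondition]]:
    """Random landscape/condition fixtures for property-based suites.

    Energies are uniform over the given ranges (|dG| capped at 100 kJ/mol),
    BEP coefficients uniform over ``alpha_range``, reference rate constants
    log-uniform over ``logk_range`` (log10), and [S] log-uniform.  With
    ``complementary_alphas=True`` alpha2 is set to 1 - alpha1, the regime
    where the closed-form optimum applies.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for lo, hi in (dG1_range, dGT_range):
        if max(abs(lo), abs(hi)) > 100.0:
            raise ValueError("|dG| ranges must stay within 100 kJ/mol")
    if not (0.0 < alpha_range[0] <= alpha_range[1] < 1.0):
        raise ValueError("alpha_range must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        a1 = float(rng.uniform(*alpha_range))
        if complementary_alphas:
            a2 = 1.0 - a1
        else:
            a2 = float(rng.uniform(*alpha_range))
        ls = ThermoLandscape(
            dG1=float(rng.uniform(*dG1_range)),
            dGT=float(rng.uniform(*dGT_range)),
            alpha1=a1,
            alpha2=a2,
            k1_0=float(10.0 ** rng.uniform(*logk_range)),
            k2_0=float(10.0 ** rng.uniform(*logk_range)),
        )
        cond = AssayCondition(S=float(10.0 ** rng.uniform(*S_range_log10)))
        out.append((ls, cond))
    return out
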