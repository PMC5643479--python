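"""Synthetic DNA-SIP experiment generator with known ground truth.

Emulates the statistical structure of an isopycnic-centrifugation
stable-isotope-probing experiment: each taxon's DNA bands as a Gaussian
around a mean buoyant density set by its GC content plus a shift
proportional to its heavy-isotope atom-fraction excess; fractions are
collected bottom-first, pooled by density window, and pooled fractions
are sequenced as multinomial amplicon counts weighted by 16S copy
number.  The generator returns paired labeled/control gradients together
with the per-taxon truth (who incorporated label, and how much), so the
downstream activity statistic can be validated for sensitivity and
false-discovery control.

The buoyant-density model is the standard linear one for CsCl gradients:
``BD0 = 1.660 + 0.098 * GC`` g/ml for unlabeled DNA, with a maximal
full-labeling shift of 0.036 g/ml for 13C and 0.016 g/ml for 15N — the
smaller 15N shift is why 15N gradients need finer fractionation and
longer spins.  Constants are overridable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gradient import (
    FractionRecord,
    GradientProfile,
    PoolingScheme,
    default_scheme,
)

__all__ = [
    "BD_INTERCEPT",
    "BD_GC_SLOPE",
    "MAX_SHIFT_G_ML",
    "GENOMES_PER_NG",
    "TaxonSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "mean_buoyant_density",
    "band_fraction_masses",
    "fraction_windows",
    "simulate_dataset",
    "default_community",
    "evaluate_detection",
]

#: Unlabeled buoyant density (g/ml) at GC = 0.
BD_INTERCEPT = 1.660
#: Buoyant-density increase per unit GC fraction (g/ml).
BD_GC_SLOPE = 0.098
#: Maximal density shift at atom-fraction excess 1.0, by isotope (g/ml).
MAX_SHIFT_G_ML = {"13C": 0.036, "15N": 0.016, "none": 0.0}
#: Bacterial genome equivalents per ng of DNA (~5 Mb genome at 650 g/mol/bp).
GENOMES_PER_NG = 1.85e5


@dataclass(frozen=True)
class TaxonSpec:
    """One community member and its labeling ground truth.

    ``atom_excess_labeled`` is the heavy-isotope atom-fraction excess the
    taxon attains under the labeled feeding treatment; 0 means the taxon
    did not assimilate the substrate.
    """

    name: str
    lineage: str
    base_abundance: float
    gc_content: float
    copy_number_16s: float = 1.0
    atom_excess_labeled: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_abundance <= 1.0:
            raise ValueError(f"{self.name}: base_abundance must be in [0,1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"{self.name}: gc_content must be in (0,1)")
        if not 0.0 <= self.atom_excess_labeled <= 1.0:
            raise ValueError(f"{self.name}: atom_excess_labeled must be in [0,1]")
        if self.copy_number_16s < 1.0:
            raise ValueError(f"{self.name}: copy_number_16s must be >= 1")


@dataclass
class SimulationConfig:
    taxa: list[TaxonSpec]
    isotope: str = "13C"
    n_fractions: int = 12
    density_min: float = 1.66
    density_max: float = 1.78
    band_sigma: float = 0.006
    reads_per_pool: int = 50_000
    total_dna_ng: float = 750.0
    qpcr_cv: float = 0.10
    pooling: PoolingScheme | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("config needs at least one taxon")
        total = sum(t.base_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base abundances must sum to 1, got {total}")
        if self.isotope not in ("13C", "15N"):
            raise ValueError(f"isotope must be '13C' or '15N', got {self.isotope!r}")
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be < density_max")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.reads_per_pool <= 0:
            raise ValueError("reads_per_pool must be positive")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be non-negative")
        if self.pooling is None:
            substrate = "cellulose" if self.n_fractions <= 12 else "urea"
            self.pooling = default_scheme(substrate, self.density_min, self.density_max)

    @property
    def substrate(self) -> str:
        return "cellulose" if self.isotope == "13C" else "urea"


@dataclass
class SyntheticDataset:
    """Paired labeled/control gradients, pooled-fraction counts, and truth."""

    labeled_profile: GradientProfile
    control_profile: GradientProfile
    labeled_counts: "CountTable"
    control_counts: "CountTable"
    truth: pd.DataFrame
    pooling: PoolingScheme
    config: SimulationConfig


def mean_buoyant_density(
    gc_content: float,
    isotope: str = "none",
    atom_excess: float = 0.0,
    *,
    intercept: float = BD_INTERCEPT,
    gc_slope: float = BD_GC_SLOPE,
    max_shift: Mapping[str, float] = MAX_SHIFT_G_ML,
) -> float:
    """Mean CsCl buoyant density (g/ml) of a taxon's DNA.

    Linear in GC content for unlabeled DNA, plus a shift proportional to
    the atom-fraction excess of the incorporated heavy isotope.
    """
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0,1), got {gc_content}")
    if not 0.0 <= atom_excess <= 1.0:
        raise ValueError(f"atom_excess must be in [0,1], got {atom_excess}")
    if isotope not in max_shift:
        raise ValueError(f"unknown isotope {isotope!r}; expected one of {sorted(max_shift)}")
    return intercept + gc_slope * gc_content + atom_excess * max_shift[isotope]


def fraction_windows(
    n_fractions: int, density_min: float, density_max: float
) -> list[tuple[float, float]]:
    """Equal-width collection windows, ordered densest-first as (low, high)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if not density_min < density_max:
        raise ValueError("density_min must be < density_max")
    edges = np.linspace(density_min, density_max, n_fractions + 1)
    return [
        (float(edges[i]), float(edges[i + 1])) for i in range(n_fractions - 1, -1, -1)
    ]


def band_fraction_masses(
    mean_bd: float, sigma: float, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Mass proportion of a Gaussian DNA band captured by each window.

    Windows must be contiguous, non-overlapping and ordered densest-first.
    Proportions are Gaussian integrals over each window renormalized to
    sum to 1 over the collected windows (mass banding outside the
    collected range is attributed proportionally).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(windows) == 0:
        raise ValueError("empty window set")
    for (lo_a, hi_a), (lo_b, hi_b) in zip(windows, windows[1:]):
        if not math.isclose(lo_a, hi_b, abs_tol=1e-9):
            raise ValueError("windows must be contiguous and ordered densest-first")
    lows = np.array([w[0] for w in windows])
    highs = np.array([w[1] for w in windows])
    raw = norm.cdf(highs, loc=mean_bd, scale=sigma) - norm.cdf(
        lows, loc=mean_bd, scale=sigma
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError("band lies entirely outside the collected windows")
    return raw / total


def _taxon_fraction_masses(
    config: SimulationConfig, labeled: bool
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-taxon x per-fraction DNA mass (ng), noiseless."""
    windows = fraction_windows(
        config.n_fractions, config.density_min, config.density_max
    )
    masses = np.empty((len(config.taxa), len(windows)))
    for i, taxon in enumerate(config.taxa):
        excess = taxon.atom_excess_labeled if labeled else 0.0
        bd = mean_buoyant_density(taxon.gc_content, config.isotope, excess)
        props = band_fraction_masses(bd, config.band_sigma, windows)
        masses[i] = config.total_dna_ng * taxon.base_abundance * props
    return masses, windows


def _profile_from_masses(
    config: SimulationConfig,
    masses: np.ndarray,
    windows: Sequence[tuple[float, float]],
    treatment: str,
    rng: np.random.Generator,
) -> GradientProfile:
    copy_numbers = np.array([t.copy_number_16s for t in config.taxa])
    dna_ng = masses.sum(axis=0)
    copies = (masses * copy_numbers[:, None]).sum(axis=0) * GENOMES_PER_NG
    if config.qpcr_cv > 0:
        # mean-one lognormal multiplicative noise with the requested CV
        log_sd = math.sqrt(math.log1p(config.qpcr_cv**2))
        copies = copies * rng.lognormal(-0.5 * log_sd**2, log_sd, size=copies.shape)
    records = [
        FractionRecord(
            index=i + 1,
            density_g_ml=(lo + hi) / 2.0,
            dna_ng=float(dna_ng[i]),
            copies_16s=float(copies[i]),
        )
        for i, (lo, hi) in enumerate(windows)
    ]
    return GradientProfile(
        fractions=records,
        substrate=config.substrate,
        treatment=treatment,
        life_stage="larva",
    )


def _pooled_counts(
    config: SimulationConfig,
    masses: np.ndarray,
    windows: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> "CountTable":
    from .activity import CountTable

    scheme = config.pooling
    midpoints = [(lo + hi) / 2.0 for lo, hi in windows]
    assignment = [scheme.assign(d) for d in midpoints]
    copy_numbers = np.array([t.copy_number_16s for t in config.taxa])
    counts: dict[str, np.ndarray] = {}
    for pool in scheme.names:
        member = [j for j, a in enumerate(assignment) if a == pool]
        if not member:
            raise ValueError(
                f"pooling window {pool!r} captures no fraction; adjust bounds"
            )
        # amplicon template share: pooled DNA mass weighted by 16S copy number
        weights = (masses[:, member].sum(axis=1)) * copy_numbers
        total = weights.sum()
        if total <= 0:
            counts[pool] = np.zeros(len(config.taxa), dtype=np.int64)
            continue
        counts[pool] = rng.multinomial(config.reads_per_pool, weights / total)
    frame = pd.DataFrame(counts, index=[t.name for t in config.taxa])
    lineages = pd.Series(
        {t.name: t.lineage for t in config.taxa}, name="taxonomy"
    )
    return CountTable(frame, lineages)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generative model for one paired SIP experiment.

    All randomness derives from ``config.seed`` through four spawned
    streams (qPCR noise and amplicon counts, for labeled and control
    gradients separately), so identical configs give identical datasets.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_qpcr_lab, rng_qpcr_ctl, rng_reads_lab, rng_reads_ctl = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    masses_lab, windows = _taxon_fraction_masses(config, labeled=True)
    masses_ctl, _ = _taxon_fraction_masses(config, labeled=False)
    labeled_profile = _profile_from_masses(
        config, masses_lab, windows, "labeled", rng_qpcr_lab
    )
    control_profile = _profile_from_masses(
        config, masses_ctl, windows, "control", rng_qpcr_ctl
    )
    labeled_counts = _pooled_counts(config, masses_lab, windows, rng_reads_lab)
    control_counts = _pooled_counts(config, masses_ctl, windows, rng_reads_ctl)
    truth = pd.DataFrame(
        {
            "taxon": [t.name for t in config.taxa],
            "labeled": [t.atom_excess_labeled > 0 for t in config.taxa],
            "atom_excess": [t.atom_excess_labeled for t in config.taxa],
        }
    ).set_index("taxon")
    return SyntheticDataset(
        labeled_profile=labeled_profile,
        control_profile=control_profile,
        labeled_counts=labeled_counts,
        control_counts=control_counts,
        truth=truth,
        pooling=config.pooling,
        config=config,
    )


def default_community(
    n_taxa: int = 30,
    n_labeled: int = 3,
    atom_excess: float = 0.75,
    seed: int | np.random.Generator = 0,
    gc_range: tuple[float, float] = (0.35, 0.65),
    copy_number_range: tuple[int, int] = (1, 7),
) -> list[TaxonSpec]:
    """A realistic gut-community stand-in: uneven Dirichlet abundances,
    mid-range GC contents, 16S copy numbers between 1 and 7, and a small
    set of truly labeled members."""
    if not 0 <= n_labeled <= n_taxa:
        raise ValueError("n_labeled must be between 0 and n_taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abundances = rng.dirichlet(np.ones(n_taxa))
    abundances = abundances / abundances.sum()
    gc = rng.uniform(*gc_range, size=n_taxa)
    copies = rng.integers(copy_number_range[0], copy_number_range[1] + 1, size=n_taxa)
    labeled_idx = set(rng.choice(n_taxa, size=n_labeled, replace=False).tolist())
    taxa = []
    for i in range(n_taxa):
        fam = f"Family_{i // 3:02d}"
        taxa.append(
            TaxonSpec(
                name=f"OTU_{i:03d}",
                lineage=(
                    "k__Bacteria; p__Phylum_0; c__Class_0; o__Order_0; "
                    f"f__{fam}; g__Genus_{i:02d}"
                ),
                base_abundance=float(abundances[i]),
                gc_content=float(gc[i]),
                copy_number_16s=float(copies[i]),
                atom_excess_labeled=atom_excess if i in labeled_idx else 0.0,
            )
        )
    # exact unit sum despite float division
    total = sum(t.base_abundance for t in taxa)
    taxa[0] = replace(taxa[0], base_abundance=taxa[0].base_abundance + (1.0 - total))
    return taxa


def evaluate_detection(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float = 0.05,
    require_positive: bool = True,
) -> dict[str, float]:
    """Score activity calls against simulation truth.

    A taxon is *flagged* if any of its dense-pool records has adjusted
    p below ``alpha`` (and positive activity A, unless
    ``require_positive`` is off).  Returns sensitivity, specificity and
    the false discovery proportion among flagged taxa.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    taxa = set(records["taxon"]) | set(truth.index)
    if not set(records["taxon"]) <= set(truth.index):
        raise ValueError("activity records mention taxa absent from truth")
    sig = records["q"] < alpha
    if require_positive:
        sig &= records["A"] > 0
    flagged = set(records.loc[sig, "taxon"])
    labeled = set(truth.index[truth["labeled"]])
    unlabeled = taxa - labeled
    tp = len(flagged & labeled)
    fp = len(flagged - labeled)
    sensitivity = tp / len(labeled) if labeled else float("nan")
    specificity = (
        len(unlabeled - flagged) / len(unlabeled) if unlabeled else float("nan")
    )
    fdp = fp / len(flagged) if flagged else 0.0
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "fdp": fdp,
        "n_flagged": float(len(flagged)),
        "n_labeled": float(len(labeled)),
    }
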