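"""Panel evaluation: per-group MAF, polymorphism summaries, allele-sharing
distances, principal coordinates analysis, and a diagnostic-allele
admixture index for hybrid flagging.

Genotypes are coded as copies of the panel-wide minor allele
(0/1/2, NaN for missing).  The minor allele is defined once across all
individuals, then per-group frequencies are folded to <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    MissingDistanceError,
)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype codes: 0/1/2 minor-allele copies, NaN missing."""

    individuals: List[str]
    loci: List[str]
    calls: np.ndarray  # float array, shape (n_individuals, n_loci)
    group_of: Dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ConfigurationError("calls: shape must match id lists")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ConfigurationError("calls: codes restricted to {0, 1, 2, NaN}")
        missing = [i for i in self.individuals if i not in self.group_of]
        if missing:
            raise ConfigurationError(f"group_of: no group for {missing[0]!r}")

    def groups(self) -> List[str]:
        return sorted(set(self.group_of[i] for i in self.individuals))

    def rows_for_group(self, group: str) -> np.ndarray:
        return np.array([k for k, ind in enumerate(self.individuals)
                         if self.group_of[ind] == group], dtype=int)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.calls, index=self.individuals, columns=self.loci)
        df.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path, group_of: Mapping[str, str]) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(
            individuals=list(df.index),
            loci=list(df.columns),
            calls=df.to_numpy(dtype=float),
            group_of=dict(group_of),
        )


@dataclass
class MAFTable:
    """Per-(group, locus) minor-allele frequencies plus sample counts."""

    frequencies: pd.DataFrame  # groups x loci, values in [0, 0.5] or NaN
    valid_n: pd.DataFrame      # non-missing individuals per (group, locus)


# ---------------------------------------------------------------------------
# MAF and polymorphism summaries
# ---------------------------------------------------------------------------

def fold(frequency: float) -> float:
    """Fold an allele frequency to the minor side (<= 0.5)."""
    return min(frequency, 1.0 - frequency)


def compute_maf(genotypes: GenotypeMatrix) -> MAFTable:
    """Per-group frequency of the panel-wide minor allele, folded to <= 0.5."""
    groups = genotypes.groups()
    for group in groups:
        if len(genotypes.rows_for_group(group)) == 0:
            raise ConfigurationError(f"group_of: empty group {group!r}")

    calls = genotypes.calls
    # panel-wide orientation: is the coded allele the global minor one?
    with np.errstate(invalid="ignore"):
        total_copies = np.nansum(calls, axis=0)
        total_n = np.sum(~np.isnan(calls), axis=0)
    panel_freq = np.divide(total_copies, 2.0 * total_n,
                           out=np.full(calls.shape[1], np.nan),
                           where=total_n > 0)
    coded_is_minor = panel_freq <= 0.5

    freq_rows = []
    n_rows = []
    for group in groups:
        rows = genotypes.rows_for_group(group)
        sub = calls[rows]
        copies = np.nansum(sub, axis=0)
        n = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            f = np.divide(copies, 2.0 * n,
                          out=np.full(sub.shape[1], np.nan), where=n > 0)
        f = np.where(coded_is_minor, f, 1.0 - f)
        f = np.minimum(f, 1.0 - f)  # fold within the group
        freq_rows.append(f)
        n_rows.append(n)
    return MAFTable(
        frequencies=pd.DataFrame(freq_rows, index=groups, columns=genotypes.loci),
        valid_n=pd.DataFrame(n_rows, index=groups, columns=genotypes.loci),
    )


def summarize_polymorphism(
    maf: MAFTable,
    high_threshold: float = 0.3,
    include_zero_in_average: bool = True,
) -> pd.DataFrame:
    """Per-group counts of polymorphic and highly polymorphic loci.

    ``average_maf`` is taken over all loci (zeros included) by default;
    ``average_maf_polymorphic`` restricts to nonzero loci.  The MAF
    range is reported over polymorphic loci.
    """
    rows = []
    for group, series in maf.frequencies.iterrows():
        values = series.dropna()
        nonzero = values[values > 0]
        rows.append({
            "group": group,
            "polymorphic": int((values > 0).sum()),
            "highly_polymorphic": int((values >= high_threshold).sum()),
            "average_maf": float(values.mean()) if len(values) else float("nan"),
            "average_maf_polymorphic": (
                float(nonzero.mean()) if len(nonzero) else 0.0
            ),
            "maf_min": float(nonzero.min()) if len(nonzero) else 0.0,
            "maf_max": float(nonzero.max()) if len(nonzero) else 0.0,
        })
    df = pd.DataFrame(rows).set_index("group")
    if not include_zero_in_average:
        df["average_maf"] = df["average_maf_polymorphic"]
    return df


# ---------------------------------------------------------------------------
# allele-sharing distance
# ---------------------------------------------------------------------------

def allele_sharing_distance(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """d(i, j) = 1 - shared allele copies / (2 * jointly-typed loci).

    With codes a, b the shared copies at a locus equal 2 - |a - b|, so
    the distance is the mean of |a - b| / 2 over pairwise-complete loci.
    """
    if len(genotypes.individuals) < 2:
        raise ConfigurationError("individuals: need >= 2 for distances")
    calls = genotypes.calls
    n = calls.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            if not both.any():
                raise MissingDistanceError(
                    f"no jointly-typed loci for pair "
                    f"({genotypes.individuals[i]}, {genotypes.individuals[j]})"
                )
            d = float(np.mean(np.abs(calls[i, both] - calls[j, both])) / 2.0)
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=genotypes.individuals,
                        columns=genotypes.individuals)


# ---------------------------------------------------------------------------
# principal coordinates analysis (classical metric scaling)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # individuals x axes
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    variance_explained: np.ndarray  # percent of the positive-eigenvalue total

    def cumulative_variance(self, n_axes: int) -> float:
        """Summed percent variance over the first ``n_axes`` axes."""
        return float(np.sum(self.variance_explained[:n_axes]))


def combined_variance(axis_percents: Sequence[float]) -> float:
    """Cumulative variance from already-expressed per-axis percentages."""
    return float(np.sum(axis_percents))


def pcoa(
    d: Union[pd.DataFrame, np.ndarray], n_axes: Optional[int] = None
) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Double-centers -D^2/2, takes the symmetric eigendecomposition, and
    scales eigenvectors by the square roots of the positive eigenvalues.
    ``variance_explained`` is each positive eigenvalue over the positive
    total, in percent.  Axis signs are fixed so the first nonzero
    loading of each axis is positive.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        matrix = d.to_numpy(dtype=float)
    else:
        matrix = np.asarray(d, dtype=float)
        labels = [f"obj{i}" for i in range(matrix.shape[0])]
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ConfigurationError("d: must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ConfigurationError("d: must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-8):
        raise ConfigurationError("d: diagonal must be zero")

    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * centering @ (matrix ** 2) @ centering
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    if not positive.any():
        raise DegenerateInputError("no positive eigenvalues in the Gram matrix")
    eigvals = eigvals[positive]
    eigvecs = eigvecs[:, positive]
    coords = eigvecs * np.sqrt(eigvals)
    for k in range(coords.shape[1]):
        nonzero = np.nonzero(np.abs(coords[:, k]) > 1e-12)[0]
        if nonzero.size and coords[nonzero[0], k] < 0:
            coords[:, k] = -coords[:, k]
    variance = 100.0 * eigvals / eigvals.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        eigvals = eigvals[:n_axes]
        variance_kept = variance[:n_axes]
    else:
        variance_kept = variance
    columns = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=columns),
        eigenvalues=eigvals,
        variance_explained=variance_kept,
    )


# ---------------------------------------------------------------------------
# diagnostic-allele admixture index
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureReport:
    fractions: pd.DataFrame  # individuals x groups, NaN when undetermined
    hybrid_flags: pd.Series  # bool per individual


def admixture_index(
    genotypes: GenotypeMatrix,
    diagnostic_loci: Mapping[str, str],
    flag_threshold: float = 0.10,
) -> AdmixtureReport:
    """Ancestry fractions from counts of group-diagnostic allele copies.

    ``diagnostic_loci`` maps locus id -> focal group; the diagnostic
    allele is the coded (minor) allele of that locus.  For individual i,
    the raw fraction for group G is diagnostic copies over 2x the
    non-missing G-loci, then fractions are normalized across groups.  A
    hybrid flag is raised when the second-largest fraction reaches
    ``flag_threshold``.
    """
    import logging

    logger = logging.getLogger(__name__)
    groups_with_loci: Dict[str, List[int]] = {}
    locus_index = {locus: k for k, locus in enumerate(genotypes.loci)}
    for locus, group in diagnostic_loci.items():
        if locus in locus_index:
            groups_with_loci.setdefault(group, []).append(locus_index[locus])
    all_groups = genotypes.groups()
    for group in all_groups:
        if group not in groups_with_loci:
            logger.warning("admixture index: no diagnostic loci for group %s; "
                           "group omitted", group)
    groups = sorted(groups_with_loci)

    rows = []
    flags = []
    for i, individual in enumerate(genotypes.individuals):
        raw = {}
        for group in groups:
            idx = groups_with_loci[group]
            calls = genotypes.calls[i, idx]
            ok = ~np.isnan(calls)
            raw[group] = (float(np.sum(calls[ok])) / (2.0 * ok.sum())
                          if ok.any() else np.nan)
        values = np.array([raw[g] for g in groups])
        total = np.nansum(values)
        if np.all(np.isnan(values)) or total == 0:
            normalized = (np.full(len(groups), np.nan)
                          if np.all(np.isnan(values))
                          else np.zeros(len(groups)))
            flags.append(False)
        else:
            normalized = np.where(np.isnan(values), 0.0, values) / total
            top_two = np.sort(normalized)[::-1][:2]
            flags.append(bool(len(top_two) > 1 and top_two[1] >= flag_threshold))
        rows.append(normalized)
    fractions = pd.DataFrame(rows, index=genotypes.individuals, columns=groups)
    return AdmixtureReport(
        fractions=fractions,
        hybrid_flags=pd.Series(flags, index=genotypes.individuals),
    )


# ---------------------------------------------------------------------------
# genotype construction from truth panels / validated loci
# ---------------------------------------------------------------------------

def genotypes_from_panel(panel, loci) -> GenotypeMatrix:
    """Genotype the panel's sequenced individuals at validated loci.

    Codes count copies of each locus's minor (diagnostic) allele on the
    individual's two truth haplotypes.
    """
    individuals = panel.individuals()
    locus_ids = [locus.locus_id for locus in loci]
    calls = np.zeros((len(individuals), len(loci)))
    for j, locus in enumerate(loci):
        cand = locus.candidate
        for i, ind in enumerate(individuals):
            copies = 0
            for hap in (0, 1):
                base = panel.haplotype_base(ind, cand.contig, hap, cand.pos0)
                if base == cand.minor_allele:
                    copies += 1
            calls[i, j] = copies
    return GenotypeMatrix(
        individuals=individuals,
        loci=locus_ids,
        calls=calls,
        group_of=dict(panel.group_map),
    )


def simulate_diversity_genotypes(
    panel,
    loci,
    n_per_group: int = 10,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw fresh per-group individuals from truth allele frequencies.

    Group allele frequencies come from the sequenced panel's haplotypes;
    new diploid genotypes are binomial draws, optionally with missing
    calls.
    """
    rng = np.random.default_rng(seed)
    sequenced = genotypes_from_panel(panel, loci)
    groups = sequenced.groups()
    freqs = {}
    for group in groups:
        rows = sequenced.rows_for_group(group)
        sub = sequenced.calls[rows]
        freqs[group] = np.nansum(sub, axis=0) / (2.0 * sub.shape[0])
    individuals = []
    group_of = {}
    rows = []
    for group in groups:
        for k in range(n_per_group):
            ind = f"{group}_v{k + 1}"
            individuals.append(ind)
            group_of[ind] = group
            draw = rng.binomial(2, freqs[group]).astype(float)
            if missing_rate > 0:
                draw[rng.random(len(draw)) < missing_rate] = np.nan
            rows.append(draw)
    return GenotypeMatrix(
        individuals=individuals,
        loci=list(sequenced.loci),
        calls=np.array(rows),
        group_of=group_of,
    )
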