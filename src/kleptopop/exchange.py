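"""Genome-exchange diagnostics.

A unisexual lineage without genome exchange accumulates variation only by
stepwise microsatellite mutation, so (i) its alleles cluster tightly around
the clonal founder alleles, (ii) its J- and L-haplomes show similar numbers
of non-clonal ("alternative") alleles, and (iii) its genetic variation lies
mainly among isolated sites.  Genome exchange with sympatric sexual hosts
breaks all three symmetries for the L-haplome: host alleles many mutation
steps away appear ("highly divergent alleles"), L-diversity outstrips
J-diversity, and variation concentrates within sites.  This module computes
those diagnostics: divergent-allele detection, carrier frequencies and the
probability of never sampling a carrier, ploidy-weighted haplome counts,
rarefied allelic richness, alternative alleles per locus, and the
PERMDISP-style partition of dispersion around group centroids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import DistanceMatrix, IndividualRecord, KleptopopError
from .partition import consensus_genotype, haplome_dose


def mutation_steps(a: int, b: int, motif_length: int) -> int:
    """Number of single-repeat mutation steps between two allele sizes."""
    if motif_length <= 0:
        raise KleptopopError("motif_length must be positive")
    return round(abs(a - b) / motif_length)


# ---------------------------------------------------------------------------
# divergent alleles


@dataclass
class DivergentAlleleSet:
    """Alleles flagged as highly divergent per isolocus, with the
    mutation-step gap separating each from the main allele cluster."""

    threshold: int
    flagged: dict[str, dict[int, int]] = field(default_factory=dict)

    def alleles(self, iso: str) -> set[int]:
        return set(self.flagged.get(iso, {}))

    def is_empty(self) -> bool:
        return all(not v for v in self.flagged.values())


def detect_divergent_alleles(
    allele_freqs: dict[str, dict[int, float]],
    motif_lengths: dict[str, int],
    gap_threshold: int = 8,
) -> DivergentAlleleSet:
    """Flag alleles separated from the main allele cluster by large gaps.

    Alleles at each isolocus are chained into clusters: consecutive (sorted)
    alleles closer than ``gap_threshold`` mutation steps belong to the same
    cluster.  The largest cluster is the main distribution; every allele
    outside it is flagged with its step gap to the nearest main-cluster
    allele.  Two equally large clusters are ambiguous and raise an error.
    """
    out = DivergentAlleleSet(threshold=gap_threshold)
    for iso, freqs in allele_freqs.items():
        alleles = sorted(freqs)
        out.flagged[iso] = {}
        if len(alleles) < 2:
            continue
        motif = motif_lengths[iso]
        clusters = [[alleles[0]]]
        for a in alleles[1:]:
            if mutation_steps(a, clusters[-1][-1], motif) >= gap_threshold:
                clusters.append([a])
            else:
                clusters[-1].append(a)
        if len(clusters) == 1:
            continue
        sizes = [len(c) for c in clusters]
        biggest = max(sizes)
        if sizes.count(biggest) > 1:
            raise KleptopopError(
                f"{iso}: two allele clusters of equal size {biggest}; "
                "designate the main cluster manually"
            )
        main = clusters[sizes.index(biggest)]
        for cluster in clusters:
            if cluster is main:
                continue
            for a in cluster:
                gap = min(mutation_steps(a, m, motif) for m in main)
                out.flagged[iso][a] = gap
    return out


def carrier_frequency(
    individuals: list[IndividualRecord],
    divergent: DivergentAlleleSet,
    iso: str,
    mode: str = "copies",
) -> float:
    """Percentage of divergent alleles at one isolocus in a set of individuals.

    ``mode='copies'``: share of haplome copies ("all possible alleles")
    occupied by divergent alleles, splitting unresolved multiplicities
    uniformly over the observed alleles.  ``mode='individuals'``: share of
    individuals carrying at least one divergent allele.  Returns NaN when no
    individual has data at the isolocus.
    """
    flagged = divergent.alleles(iso)
    total = 0.0
    hits = 0.0
    for ind in individuals:
        alleles = ind.isoloci.get(iso, ())
        if not alleles:
            continue
        if mode == "individuals":
            total += 1
            hits += bool(flagged & set(alleles))
            continue
        dose = max(_dose_at(ind, iso), len(alleles))
        per_allele = dose / len(alleles)  # 1 certain + uniform split remainder
        total += dose
        hits += per_allele * sum(1 for a in alleles if a in flagged)
    if total == 0:
        return float("nan")
    return 100.0 * hits / total


def _dose_at(ind, iso: str) -> int:
    if iso.endswith("-J"):
        return haplome_dose(ind, "J")
    if iso.endswith("-L"):
        return haplome_dose(ind, "L")
    return haplome_dose(ind, "J") + haplome_dose(ind, "L")


def prob_no_carrier(p_mean: float, n: int) -> float:
    """Probability of sampling ``n`` individuals without any divergent-allele
    carrier when the mean per-individual carrier frequency is ``p_mean``."""
    if not 0 <= p_mean <= 1:
        raise KleptopopError("p_mean must be in [0, 1]")
    if n < 0:
        raise KleptopopError("n must be nonnegative")
    return (1.0 - p_mean) ** n


# ---------------------------------------------------------------------------
# ploidy-weighted counts and rarefied richness


def weighted_haplome_count(individuals: list[IndividualRecord], haplome: str) -> int:
    """Total copies of a haplome across a group (n for that locus set).

    LL contributes 2 L / 0 J, LJ 1/1, LLJ 2/1, LLLJ 3/1; UNCALLED biotypes
    are excluded with a warning.
    """
    total = 0
    for ind in individuals:
        if ind.biotype == "UNCALLED":
            warnings.warn(f"{ind.id}: biotype UNCALLED excluded", stacklevel=2)
            continue
        total += haplome_dose(ind, haplome)
    return total


def weighted_ploidy_level(individuals: list[IndividualRecord], haplome: str) -> float:
    """Mean haplome copies per individual (weighted ploidy level)."""
    called = [ind for ind in individuals if ind.biotype != "UNCALLED"]
    if not called:
        raise KleptopopError("weighted ploidy of an empty (or uncalled) group")
    return weighted_haplome_count(called, haplome) / len(called)


def rarefied_allele_count(copy_counts: dict[int, float], n_rarefy: float) -> float:
    """Expected number of distinct alleles in a subsample of ``n_rarefy``
    copies (hypergeometric rarefaction).

    ``sum_a [1 - C(N - N_a, n) / C(N, n)]`` with N the total copies.  Counts
    may be fractional (uniformly split partial heterozygotes); the binomial
    ratio is then evaluated as the corresponding falling-factorial product,
    which coincides with the exact hypergeometric expectation for integer
    counts.
    """
    if n_rarefy <= 0:
        raise KleptopopError("rarefaction size must be positive")
    total = float(sum(copy_counts.values()))
    n = int(round(n_rarefy))
    if n > round(total + 1e-9):
        raise KleptopopError(f"cannot rarefy {total:g} copies to {n}")
    expected = 0.0
    for count in copy_counts.values():
        # P(allele absent from subsample) = prod_{i<n} (N - N_a - i) / (N - i)
        p_absent = 1.0
        for i in range(n):
            num = total - count - i
            if num <= 0:
                p_absent = 0.0
                break
            p_absent *= num / (total - i)
        expected += 1.0 - p_absent
    return expected


def allele_copy_counts(
    individuals: list[IndividualRecord], iso: str
) -> dict[int, float]:
    """Weighted allele copy counts at an isolocus (uniform split of
    unresolved multiplicities)."""
    counts: dict[int, float] = {}
    for ind in individuals:
        alleles = ind.isoloci.get(iso, ())
        if not alleles:
            continue
        dose = max(_dose_at(ind, iso), len(alleles))
        per = dose / len(alleles)
        for a in alleles:
            counts[a] = counts.get(a, 0.0) + per
    return counts


def alternative_alleles_per_locus(
    unit: list[IndividualRecord],
    isoloci: list[str],
    n_rarefy: float,
    consensus_of: list[IndividualRecord] | None = None,
    baseline: str = "consensus",
) -> float:
    """Mean number of non-clonal alleles per locus, controlled for ploidy.

    Per isolocus: hypergeometric-rarefied allele count of the unit minus the
    number of distinct alleles strict clonality would show.  The clonal
    baseline is the distinct-allele count of the group's consensus (modal)
    genotype (``baseline='consensus'``) or the minimum distinct count over
    individuals (``baseline='min'``).  Differences are floored at zero and
    averaged over the locus set; loci without data are skipped with a warning.
    """
    if baseline not in ("consensus", "min"):
        raise KleptopopError(f"unknown baseline {baseline!r}")
    ref = consensus_of if consensus_of is not None else unit
    cons = consensus_genotype(ref, isoloci) if baseline == "consensus" else None
    values = []
    for iso in isoloci:
        counts = allele_copy_counts(unit, iso)
        if not counts:
            warnings.warn(f"no data at isolocus {iso}; skipped", stacklevel=2)
            continue
        total = sum(counts.values())
        rarefied = rarefied_allele_count(counts, min(n_rarefy, total))
        if baseline == "consensus":
            base = len(cons.get(iso, ()))
            if base == 0:
                base = 1
        else:
            base = min(
                len(ind.isoloci[iso]) for ind in unit if ind.isoloci.get(iso)
            )
        values.append(max(0.0, rarefied - base))
    if not values:
        raise KleptopopError("no isolocus with data")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# dispersion partitioning (PERMDISP-style)


@dataclass
class DispersionPartition:
    """Per-group centroid dispersion and its inter/intra-site partition."""

    table: pd.DataFrame  # index: group; columns below
    #: per-individual distances, for ANOVA/Tukey comparisons
    individual: pd.DataFrame  # columns: id, group, site, d_total, d_intra


def _pcoa_embedding(dm: DistanceMatrix):
    """Principal-coordinates embedding keeping negative-eigenvalue axes.

    Returns (real_coords, imag_coords): squared distances in the embedding
    are (real part) - (imaginary part), the standard PERMDISP treatment of
    semi-metric dissimilarities.
    """
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-9 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def _centroid_distances(real, imag, members: np.ndarray) -> np.ndarray:
    """Distance of each member to the members' centroid in the split
    real/imaginary embedding, floored at zero."""
    cr = real[members].mean(axis=0)
    ci = imag[members].mean(axis=0) if imag.shape[1] else np.zeros(0)
    d2 = ((real[members] - cr) ** 2).sum(axis=1)
    if imag.shape[1]:
        d2 = d2 - ((imag[members] - ci) ** 2).sum(axis=1)
    if (d2 < -1e-8).any():
        warnings.warn("negative squared centroid distance floored at 0", stacklevel=2)
    return np.sqrt(np.clip(d2, 0.0, None))


def dispersion_partition(
    dm: DistanceMatrix,
    groups: dict[str, str],
    sites: dict[str, str],
) -> DispersionPartition:
    """Partition each group's centroid dispersion into inter- and intra-site
    components.

    ``total`` is the mean distance of a group's members to the group
    centroid; ``intra`` the mean distance to their own (group x site)
    centroid; ``inter = total - intra``.  Percentages are relative to total.
    Groups with a single member are reported as NaN.
    """
    labels = dm.labels
    real, imag = _pcoa_embedding(dm)
    idx = {lab: i for i, lab in enumerate(labels)}
    rows = []
    per_ind = []
    for grp in sorted(set(groups.values())):
        members = [l for l in labels if groups[l] == grp]
        if len(members) < 2:
            rows.append(
                {"group": grp, "n": len(members), "total": np.nan,
                 "inter": np.nan, "intra": np.nan,
                 "inter_pct": np.nan, "intra_pct": np.nan}
            )
            continue
        mi = np.array([idx[l] for l in members])
        d_total = _centroid_distances(real, imag, mi)
        d_intra = np.empty(len(members))
        for site in sorted({sites[l] for l in members}):
            sel = [k for k, l in enumerate(members) if sites[l] == site]
            d_intra[sel] = _centroid_distances(real, imag, mi[np.array(sel)])
        total = float(d_total.mean())
        intra = float(d_intra.mean())
        inter = total - intra
        if total > 0:
            inter_pct, intra_pct = 100 * inter / total, 100 * intra / total
        else:
            inter_pct = intra_pct = np.nan
        rows.append(
            {"group": grp, "n": len(members), "total": total, "inter": inter,
             "intra": intra, "inter_pct": inter_pct, "intra_pct": intra_pct}
        )
        for k, l in enumerate(members):
            per_ind.append(
                {"id": l, "group": grp, "site": sites[l],
                 "d_total": d_total[k], "d_intra": d_intra[k]}
            )
    table = pd.DataFrame(rows).set_index("group")
    return DispersionPartition(table=table, individual=pd.DataFrame(per_ind))


def compare_dispersions(values, labels, alpha: float = 0.05) -> dict:
    """One-way ANOVA plus Tukey HSD compact letter display.

    ``values`` are per-individual distances to centroid, ``labels`` the group
    of each.  Groups that share a letter are not significantly different at
    ``alpha``.  With zero variance everywhere the F statistic is undefined
    and reported as NaN (all groups share one letter).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise KleptopopError("need at least two groups")
    samples = [values[labels == g] for g in group_names]
    if any(len(s) < 2 for s in samples):
        raise KleptopopError("every group needs at least two members")
    if all(np.ptp(s) == 0 for s in samples):
        return {
            "F": float("nan"), "p": float("nan"),
            "letters": {g: "a" for g in group_names},
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_val = stats.f_oneway(*samples)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    different = set()
    for (g1, g2), reject in zip(
        itertools.combinations(tukey.groupsunique, 2), tukey.reject
    ):
        if reject:
            different.add(frozenset((g1, g2)))
    letters = _compact_letters(group_names, different,
                               order=np.argsort([-s.mean() for s in samples]))
    return {"F": float(f_stat), "p": float(p_val), "letters": letters}


def _compact_letters(groups, different, order=None) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter covering all groups and splits it for every
    significantly different pair, then drops letter sets contained in others.
    """
    ordered = [groups[i] for i in order] if order is not None else list(groups)
    sets: list[set] = [set(ordered)]
    for pair in sorted(different, key=lambda fs: sorted(fs)):
        g1, g2 = sorted(pair)
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.extend([s - {g1}, s - {g2}])
        # absorb subsets
        sets = [s for s in sets if not any(s < t for t in sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(ordered.index(g) for g in s))
    letters = {g: "" for g in groups}
    for k, s in enumerate(sets):
        letter = chr(ord("a") + k)
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}
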