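"""Bruvo-type microsatellite genotype distances for mixed ploidy.

The single-allele dissimilarity follows the stepwise mutation model:
``d = 1 - 2**(-x)`` where ``x`` is the number of repeat-unit steps between
two allele sizes.  Genotype distances for equal ploidy minimize the mean
allele dissimilarity over all one-to-one allele assignments.  For unequal
ploidy the smaller genotype is completed with "virtual" alleles — drawn from
its own alleles (genome addition) or from the larger genotype's alleles
(genome loss) — enumerating every completion and averaging; when both models
are requested their results are averaged.  Partial heterozygotes (unresolved
multiplicities) are handled by enumerating every completion to the known copy
number, weighted by reference allele frequencies.

Ploidy never exceeds 4 in this complex, so all enumerations are exhaustive
and exact (at most 4! assignments, 4**3 virtual completions).
"""

from __future__ import annotations

import itertools
import math
import warnings
from functools import lru_cache

import numpy as np

from .model import Dataset, DistanceMatrix, KleptopopError
from .partition import IsolocusMap, haplome_dose


def allele_step_distance(a: int, b: int, motif_length: int) -> float:
    """SMM dissimilarity ``1 - 2**(-x)`` between two allele sizes (bp).

    ``x = |a - b| / motif_length``; non-integer step counts (fragment-size
    jitter) are rounded to the nearest whole step with a warning.
    """
    if a < 0 or b < 0:
        raise KleptopopError("negative allele size")
    if motif_length <= 0:
        raise KleptopopError("motif_length must be positive")
    x = abs(a - b) / motif_length
    if x != int(x):
        warnings.warn(
            f"allele difference |{a}-{b}| not a multiple of motif "
            f"{motif_length}; rounding to nearest step",
            stacklevel=2,
        )
        x = round(x)
    return 1.0 - 2.0 ** (-x)


@lru_cache(maxsize=1_000_000)
def _assignment_distance(g1: tuple, g2: tuple, motif_length: int) -> float:
    """Equal-ploidy distance: min over allele assignments of the mean SMM
    dissimilarity.  Exhaustive over permutations (ploidy <= 4)."""
    k = len(g1)
    if k != len(g2):
        raise KleptopopError("assignment distance requires equal ploidy")
    if k == 0:
        raise KleptopopError("empty genotype")
    pair = [[allele_step_distance(a, b, motif_length) for b in g2] for a in g1]
    best = math.inf
    for perm in itertools.permutations(range(k)):
        tot = sum(pair[i][perm[i]] for i in range(k))
        if tot < best:
            best = tot
    return best / k


def bruvo_genotype_distance(
    g1,
    g2,
    motif_length: int,
    add: bool = True,
    loss: bool = True,
) -> float:
    """Bruvo distance between two fully resolved allele multisets.

    ``g1`` and ``g2`` are sequences of allele sizes expanded to copy number.
    With unequal ploidy, ``add`` completes the smaller multiset from its own
    distinct alleles and ``loss`` from the larger genotype's distinct alleles;
    every completion (ordered draws, so an allele appearing in several
    completions is weighted accordingly) is scored as an equal-ploidy distance
    and averaged, and the two models' means are averaged when both are set.
    """
    if not add and not loss:
        raise KleptopopError("at least one of add/loss must be enabled")
    t1 = tuple(sorted(g1))
    t2 = tuple(sorted(g2))
    if not t1 or not t2:
        raise KleptopopError("empty genotype has no distance (treat as missing)")
    if len(t1) == len(t2):
        return _assignment_distance(t1, t2, motif_length)
    small, large = (t1, t2) if len(t1) < len(t2) else (t2, t1)
    parts = []
    if add:
        parts.append(_completion_mean(small, large, sorted(set(small)), motif_length))
    if loss:
        parts.append(_completion_mean(small, large, sorted(set(large)), motif_length))
    return float(np.mean(parts))


def _completion_mean(small, large, donor_alleles, motif_length) -> float:
    deficit = len(large) - len(small)
    total = 0.0
    count = 0
    for extra in itertools.product(donor_alleles, repeat=deficit):
        completed = tuple(sorted(small + extra))
        total += _assignment_distance(completed, large, motif_length)
        count += 1
    return total / count


# ---------------------------------------------------------------------------
# allele frequencies and partial-heterozygote weighting


def estimate_allele_frequencies(
    dataset: Dataset,
    isoloci: list[str],
    scope: str = "site",
) -> dict:
    """Relative allele frequencies per isolocus within each scope unit.

    Each individual contributes weight equal to its haplome dose at the
    isolocus: every distinct observed allele receives one certain copy and
    the unresolved remainder is split uniformly among the observed alleles.

    Returns ``{unit: {isolocus: {allele: freq}}}``; for ``scope='global'``
    the single unit is ``None``.
    """
    if scope not in ("global", "site", "group"):
        raise KleptopopError(f"unknown frequency scope {scope!r}")
    counts: dict = {}
    for ind in dataset.individuals:
        unit = {"global": None, "site": ind.site, "group": ind.group}[scope]
        for iso in isoloci:
            alleles = ind.isoloci.get(iso, ())
            if not alleles:
                continue
            dose = max(_iso_dose(ind, iso), len(alleles))
            extra = (dose - len(alleles)) / len(alleles)
            tab = counts.setdefault(unit, {}).setdefault(iso, {})
            for a in alleles:
                tab[a] = tab.get(a, 0.0) + 1.0 + extra
    freqs: dict = {}
    for unit, by_iso in counts.items():
        freqs[unit] = {}
        for iso, tab in by_iso.items():
            tot = sum(tab.values())
            freqs[unit][iso] = {a: c / tot for a, c in tab.items()}
    return freqs


def _iso_dose(ind, iso: str) -> int:
    if iso.endswith("-J"):
        return haplome_dose(ind, "J")
    if iso.endswith("-L"):
        return haplome_dose(ind, "L")
    # unpartitioned isolocus: total ploidy
    return haplome_dose(ind, "J") + haplome_dose(ind, "L")


def _completions(observed, copy_number, freqs, iso):
    """All multiset completions of a partial heterozygote with weights.

    Duplicated copies are chosen among the observed alleles; each completion
    is weighted by the product of reference frequencies of its duplicate
    alleles (renormalized).  Alleles absent from the frequency table get the
    smallest frequency observed at that locus, with a warning.
    """
    deficit = copy_number - len(observed)
    if deficit <= 0:
        return [(tuple(sorted(observed)), 1.0)]
    table = dict(freqs or {})
    if table:
        floor = min(table.values())
    else:
        floor = 1.0
    missing = [a for a in observed if a not in table]
    if missing and freqs is not None:
        warnings.warn(
            f"{iso}: alleles {missing} absent from frequency table; "
            "using minimum observed frequency",
            stacklevel=3,
        )
    out = []
    total = 0.0
    for extra in itertools.combinations_with_replacement(sorted(observed), deficit):
        w = 1.0
        for a in extra:
            w *= table.get(a, floor)
        out.append((tuple(sorted(tuple(observed) + extra)), w))
        total += w
    if total <= 0:
        w = 1.0 / len(out)
        return [(g, w) for g, _ in out]
    return [(g, w / total) for g, w in out]


def weighted_partial_het_distance(
    obs1,
    copy1: int,
    obs2,
    copy2: int,
    freqs1,
    freqs2,
    motif_length: int,
    add: bool = True,
    loss: bool = True,
    iso: str = "?",
) -> float:
    """Frequency-weighted Bruvo distance between possibly ambiguous genotypes.

    Unknown alleles of each partial heterozygote are extrapolated by
    enumerating completions weighted by reference allele frequencies; the
    result is the weighted mean Bruvo distance over completion pairs.  With
    both genotypes fully resolved this reduces to ``bruvo_genotype_distance``.
    """
    comp1 = _completions(tuple(obs1), copy1, freqs1, iso)
    comp2 = _completions(tuple(obs2), copy2, freqs2, iso)
    total = 0.0
    for g1, w1 in comp1:
        for g2, w2 in comp2:
            total += w1 * w2 * bruvo_genotype_distance(
                g1, g2, motif_length, add=add, loss=loss
            )
    return total


# ---------------------------------------------------------------------------
# pairwise matrices


def per_locus_matrices(
    dataset: Dataset,
    isoloci: list[str],
    freqs: dict | None = None,
    freq_scope: str = "site",
    add: bool = True,
    loss: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Stack of per-isolocus distance matrices (NaN where data is missing).

    Returns ``(stack, labels)`` with ``stack.shape == (len(isoloci), n, n)``.
    Copy numbers come from the called biotypes (a haploid J set, 1–3 L
    copies); individuals whose observed allele count exceeds the dose keep
    the observed count.
    """
    inds = dataset.individuals
    labels = [ind.id for ind in inds]
    n = len(inds)
    if n < 2:
        raise KleptopopError("need at least two individuals")
    locus_map = dataset.locus_map
    if freqs is None:
        freqs = estimate_allele_frequencies(dataset, isoloci, scope=freq_scope)

    def unit_of(ind):
        return {"global": None, "site": ind.site, "group": ind.group}[freq_scope]

    stack = np.full((len(isoloci), n, n), np.nan)
    cache: dict = {}
    for li, iso in enumerate(isoloci):
        base = iso.rsplit("-", 1)[0]
        motif = locus_map[base].motif_length
        for i in range(n):
            a_obs = inds[i].isoloci.get(iso, ())
            if not a_obs:
                continue
            stack[li, i, i] = 0.0
            copy_i = max(_iso_dose(inds[i], iso), len(a_obs))
            fi = freqs.get(unit_of(inds[i]), {}).get(iso)
            for j in range(i + 1, n):
                b_obs = inds[j].isoloci.get(iso, ())
                if not b_obs:
                    continue
                copy_j = max(_iso_dose(inds[j], iso), len(b_obs))
                fj = freqs.get(unit_of(inds[j]), {}).get(iso)
                key = (iso, a_obs, copy_i, unit_of(inds[i]),
                       b_obs, copy_j, unit_of(inds[j]))
                if key in cache:
                    d = cache[key]
                else:
                    if copy_i == len(a_obs) and copy_j == len(b_obs):
                        d = bruvo_genotype_distance(
                            a_obs, b_obs, motif, add=add, loss=loss
                        )
                    else:
                        d = weighted_partial_het_distance(
                            a_obs, copy_i, b_obs, copy_j, fi, fj, motif,
                            add=add, loss=loss, iso=iso,
                        )
                    cache[key] = d
                stack[li, i, j] = stack[li, j, i] = d
    return stack, labels


def pairwise_matrix(
    dataset: Dataset,
    isoloci: list[str],
    freqs: dict | None = None,
    freq_scope: str = "site",
    add: bool = True,
    loss: bool = True,
) -> DistanceMatrix:
    """Mean Bruvo distance over the isoloci where both individuals have data."""
    stack, labels = per_locus_matrices(
        dataset, isoloci, freqs=freqs, freq_scope=freq_scope, add=add, loss=loss
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(stack, axis=0)
    if np.isnan(values).any():
        bad = np.argwhere(np.isnan(values))
        i, j = bad[0]
        raise KleptopopError(
            f"individuals {labels[i]} and {labels[j]} share no scored isolocus"
        )
    return DistanceMatrix(labels, values)


def matrix_from_stack(stack: np.ndarray, labels: list[str]) -> DistanceMatrix:
    """Collapse a per-locus stack (e.g. a bootstrap resample) to a matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(stack, axis=0)
    if np.isnan(values).any():
        raise KleptopopError("some pair shares no scored isolocus in this resample")
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


def isolocus_set(dataset: Dataset, which: str, isolocus_map: IsolocusMap | None = None) -> list[str]:
    """Named isolocus sets: 'J' (haploid J loci), 'L', or 'LJ' (both).

    Non-discriminating loci are excluded from all sets.
    """
    if isolocus_map is None:
        isolocus_map = IsolocusMap.from_loci(dataset.loci)
    if which == "J":
        return isolocus_map.isoloci(dataset.loci, "J")
    if which == "L":
        return isolocus_map.isoloci(dataset.loci, "L")
    if which == "LJ":
        return isolocus_map.isoloci(dataset.loci, "J") + isolocus_map.isoloci(
            dataset.loci, "L"
        )
    raise KleptopopError(f"unknown isolocus set {which!r}")
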