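"""Isolocus separation, biotype (ploidy) calling and genetic-group assignment.

Microsatellite loci in the L/J complex fall into three classes: loci that
amplify only one species' haplome, loci whose J and L allele-size ranges are
disjoint (so every allele can be attributed to a haplome), and
non-discriminating loci whose ranges overlap.  Splitting each genotype into
J- and L-"isoloci" turns a mixed-ploidy genotype into one haploid J component
and one 1–3 copy L component, which is what every downstream statistic
operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import (
    BIOTYPE_DOSE,
    Dataset,
    IndividualRecord,
    KleptopopError,
    LocusDef,
)

J_ONLY = "J_ONLY"
L_ONLY = "L_ONLY"
SPLIT_BY_RANGE = "SPLIT_BY_RANGE"
NON_DISCRIMINATING = "NON_DISCRIMINATING"


def isolocus_name(locus: str, haplome: str) -> str:
    return f"{locus}-{haplome}"


@dataclass(frozen=True)
class IsolocusMap:
    """Per-locus rule assigning alleles to haplomes."""

    rules: dict[str, str]  # locus name -> rule constant

    @classmethod
    def from_loci(cls, loci: list[LocusDef]) -> "IsolocusMap":
        """Derive the rule for each locus from its configured ranges."""
        rules = {}
        for locus in loci:
            if locus.j_range is not None and locus.l_range is not None:
                rules[locus.name] = SPLIT_BY_RANGE
            elif locus.j_range is not None:
                rules[locus.name] = J_ONLY
            elif locus.l_range is not None:
                rules[locus.name] = L_ONLY
            else:
                rules[locus.name] = NON_DISCRIMINATING
        return cls(rules)

    def isoloci(self, loci: list[LocusDef], haplome: str) -> list[str]:
        """Names of all isoloci informative for ``haplome`` ('J' or 'L')."""
        out = []
        own = {"J": J_ONLY, "L": L_ONLY}[haplome]
        for locus in loci:
            rule = self.rules.get(locus.name)
            if rule == own or rule == SPLIT_BY_RANGE:
                out.append(isolocus_name(locus.name, haplome))
        return out


def split_isoloci(dataset: Dataset, isolocus_map: IsolocusMap | None = None) -> Dataset:
    """Assign every observed allele to a J or L isolocus (in place).

    Alleles at a SPLIT_BY_RANGE locus that fall outside both configured
    ranges stay unpartitioned (isolocus ``<name>-U``) with a warning; alleles
    at non-discriminating loci all go to ``<name>-U``.
    """
    if isolocus_map is None:
        isolocus_map = IsolocusMap.from_loci(dataset.loci)
    locus_map = dataset.locus_map
    for name in locus_map:
        if name not in isolocus_map.rules:
            raise KleptopopError(f"no isolocus rule for locus {name}")
    for ind in dataset.individuals:
        ind.isoloci = {}
        for name, geno in ind.genotypes.items():
            locus = locus_map[name]
            rule = isolocus_map.rules[name]
            j, l, u = [], [], []
            for allele in geno.observed_alleles:
                if rule == J_ONLY:
                    j.append(allele)
                elif rule == L_ONLY:
                    l.append(allele)
                elif rule == NON_DISCRIMINATING:
                    u.append(allele)
                else:
                    if locus.j_range and locus.j_range[0] <= allele <= locus.j_range[1]:
                        j.append(allele)
                    elif locus.l_range and locus.l_range[0] <= allele <= locus.l_range[1]:
                        l.append(allele)
                    else:
                        warnings.warn(
                            f"{ind.id}/{name}: allele {allele} outside both "
                            "J and L ranges; left unpartitioned",
                            stacklevel=2,
                        )
                        u.append(allele)
            # conservation: every input allele lands in exactly one bucket
            assert len(j) + len(l) + len(u) == len(geno.observed_alleles)
            if j:
                ind.isoloci[isolocus_name(name, "J")] = tuple(j)
            if l:
                ind.isoloci[isolocus_name(name, "L")] = tuple(l)
            if u:
                ind.isoloci[isolocus_name(name, "U")] = tuple(u)
    return dataset


def call_biotype(ind: IndividualRecord) -> str:
    """Call haplome composition (LL, LJ, LLJ, LLLJ) from split isoloci.

    The copy number of each haplome is estimated as the maximum number of
    distinct alleles seen at any isolocus of that haplome (at least 1 if any
    allele is present).  Partial heterozygotes can only under-report copy
    number, so the maximum is a lower bound that a single informative locus
    can raise.  Compositions never observed in the study area (JJ-carrying
    or >4n) stay UNCALLED.
    """
    n_j = _haplome_copies(ind, "J")
    n_l = _haplome_copies(ind, "L")
    if n_j == 0 and n_l in (1, 2):
        ind.biotype = "LL"
    elif n_j == 1 and n_l in (1, 2, 3):
        ind.biotype = {1: "LJ", 2: "LLJ", 3: "LLLJ"}[n_l]
    else:
        ind.biotype = "UNCALLED"
    return ind.biotype


def _haplome_copies(ind: IndividualRecord, haplome: str) -> int:
    suffix = f"-{haplome}"
    counts = [
        len(alleles)
        for iso, alleles in ind.isoloci.items()
        if iso.endswith(suffix) and alleles
    ]
    return max(counts) if counts else 0


def call_biotypes(dataset: Dataset) -> Dataset:
    for ind in dataset.individuals:
        call_biotype(ind)
    return dataset


def haplome_dose(ind: IndividualRecord, haplome: str) -> int:
    """Copies of ``haplome`` implied by the called biotype (0 if UNCALLED)."""
    if ind.biotype not in BIOTYPE_DOSE:
        return 0
    n_l, n_j = BIOTYPE_DOSE[ind.biotype]
    return n_l if haplome == "L" else n_j


@dataclass(frozen=True)
class DiagnosticRuleTable:
    """Group assignment rules based on the multimodal J-loci.

    ``consensus`` gives the modal J-allele tuple at each diagnostic J-isolocus;
    ``diagnostics`` maps each group label to the (isolocus, allele) pairs that
    depart from the consensus and identify it.  An individual matching the
    consensus at every diagnostic locus belongs to the consensus group
    (``consensus_group``, group B in the study system).
    """

    consensus: dict[str, tuple[int, ...]]
    diagnostics: dict[str, tuple[tuple[str, int], ...]]
    consensus_group: str = "B"

    def __post_init__(self):
        for grp, pairs in self.diagnostics.items():
            for iso, allele in pairs:
                if iso not in self.consensus:
                    raise KleptopopError(
                        f"group {grp}: diagnostic isolocus {iso} not in consensus"
                    )
                if allele in self.consensus[iso]:
                    raise KleptopopError(
                        f"group {grp}: diagnostic allele {allele} at {iso} "
                        "equals the consensus"
                    )


def assign_group(ind: IndividualRecord, rules: DiagnosticRuleTable) -> str:
    """Assign an individual to a genetic group from its J-isoloci.

    Consensus genotype at every diagnostic locus -> consensus group; exactly
    one group's full diagnostic pattern -> that group; conflicting or novel
    patterns -> X; missing data at any diagnostic locus -> UNASSIGNED.
    """
    observed = {}
    for iso in rules.consensus:
        alleles = ind.isoloci.get(iso, ())
        if not alleles:
            warnings.warn(
                f"{ind.id}: missing data at diagnostic isolocus {iso}",
                stacklevel=2,
            )
            ind.group = "UNASSIGNED"
            return ind.group
        observed[iso] = tuple(sorted(alleles))

    consensus = {iso: tuple(sorted(a)) for iso, a in rules.consensus.items()}
    if observed == consensus:
        ind.group = rules.consensus_group
        return ind.group
    matches = [
        grp
        for grp in rules.diagnostics
        if observed == _expected_pattern(rules, grp)
    ]
    ind.group = matches[0] if len(matches) == 1 else "X"
    return ind.group


def _expected_pattern(rules: DiagnosticRuleTable, grp: str) -> dict[str, tuple[int, ...]]:
    """Consensus pattern with the group's diagnostic alleles substituted.

    The J haplome is haploid in this complex, so a diagnostic allele replaces
    the consensus allele at its locus outright.
    """
    expected = {iso: tuple(sorted(a)) for iso, a in rules.consensus.items()}
    for iso, allele in rules.diagnostics[grp]:
        expected[iso] = (allele,)
    return expected


def assign_groups(dataset: Dataset, rules: DiagnosticRuleTable) -> Dataset:
    for ind in dataset.individuals:
        assign_group(ind, rules)
    return dataset


def consensus_genotype(
    individuals: list[IndividualRecord], isoloci: list[str]
) -> dict[str, tuple[int, ...]]:
    """Modal multilocus genotype of a group over the given isoloci.

    Per isolocus the most frequent distinct-allele tuple wins; ties break to
    the lexicographically smallest allele-size vector.  Missing genotypes do
    not vote.
    """
    if not individuals:
        raise KleptopopError("consensus of an empty group")
    out = {}
    for iso in isoloci:
        counts: dict[tuple[int, ...], int] = {}
        for ind in individuals:
            alleles = tuple(sorted(ind.isoloci.get(iso, ())))
            if alleles:
                counts[alleles] = counts.get(alleles, 0) + 1
        if not counts:
            continue
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[iso] = best[0]
    return out
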