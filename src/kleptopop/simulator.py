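"""Forward-time kleptogenesis simulator.

Simulates unisexual *Ambystoma* lineages reproducing by kleptogenesis in
discrete generations.  Each female's daughter arises from one of four
events: clonal reproduction (genome copied), genome replacement (one L
haplome swapped for a sperm-donor gamete from the site's sexual host
population), ploidy elevation (host gamete appended, capped at LLLJ) or
ploidy reduction (one L haplome dropped, floored at LJ).  Microsatellites
then mutate by single repeat steps (strict SMM, reflecting at the configured
allele-size bounds).  The J haplome is never exchanged: *A. jeffersonianum*
is absent from the study region, so J variation is purely mutational — the
clonal reference against which L-haplome diversity is judged.

Host populations are stationary allele-frequency pools (a boundary
condition, not an evolving population).  Within each site and group the
population is held at constant size with Wright–Fisher resampling of
mothers, which produces the within-site shared ancestry that real clonal
ponds show; isolated sites then diverge by mutation while sites receiving
host gametes keep gaining within-site diversity.

Every simulated dataset comes with full ground truth (lineage, biotype,
ancestral event list, mutation count) so pipeline stages can be tested
against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Dataset, IndividualRecord, KleptopopError, LocusDef, MultisetGenotype
from .partition import DiagnosticRuleTable

BIOTYPE_BY_L = {1: "LJ", 2: "LLJ", 3: "LLLJ"}


@dataclass(frozen=True)
class GroupSpec:
    """Founder genotype and per-generation event rates of one lineage group."""

    label: str
    founder_j: dict[str, int]  # locus -> allele on the (haploid) J haplome
    founder_l: tuple[dict[str, int], ...]  # one mapping per L haplome
    sites: tuple[str, ...]
    exchange_rate: float = 0.0
    elevation_rate: float = 0.0
    reduction_rate: float = 0.0

    def __post_init__(self):
        rates = (self.exchange_rate, self.elevation_rate, self.reduction_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise KleptopopError(f"group {self.label}: rates must be in [0, 1]")
        if sum(rates) > 1:
            raise KleptopopError(f"group {self.label}: event rates sum above 1")
        if not 1 <= len(self.founder_l) <= 3:
            raise KleptopopError(f"group {self.label}: need 1-3 founder L haplomes")


@dataclass
class SimConfig:
    """Full parameterization of a kleptogenesis simulation."""

    loci: list[LocusDef]
    sites: pd.DataFrame  # columns: site, latitude, longitude
    groups: list[GroupSpec]
    #: site -> locus -> {allele: frequency}; loci amplifying the L haplome
    host_pools: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    #: site -> number of sexual LL individuals sampled
    host_sample: dict[str, int] = field(default_factory=dict)
    mu: float = 2e-3  # per haplome-locus per generation single-step rate
    mu_overrides: dict[str, float] = field(default_factory=dict)
    generations: int = 80
    pop_size: int = 12
    n_sampled: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mu <= 1:
            raise KleptopopError("mu must be in [0, 1]")
        if self.n_sampled > self.pop_size:
            raise KleptopopError("cannot sample more individuals than pop_size")
        for site, pools in self.host_pools.items():
            for locus, freqs in pools.items():
                tot = sum(freqs.values())
                if not np.isclose(tot, 1.0, atol=1e-9):
                    raise KleptopopError(
                        f"host pool {site}/{locus}: frequencies sum to {tot}"
                    )
        for grp in self.groups:
            needs_host = grp.exchange_rate > 0 or grp.elevation_rate > 0
            for site in grp.sites:
                if needs_host and site not in self.host_pools:
                    raise KleptopopError(
                        f"group {grp.label} exchanges at site {site} "
                        "but no host pool is defined there"
                    )

    def mutation_rate(self, locus: str) -> float:
        return self.mu_overrides.get(locus, self.mu)

    def j_loci(self) -> list[str]:
        return [l.name for l in self.loci if l.j_range is not None or not l.discriminating]

    def l_loci(self) -> list[str]:
        return [l.name for l in self.loci if l.l_range is not None or not l.discriminating]


@dataclass
class SimTruth:
    """Ground truth per sampled individual."""

    records: dict[str, dict]

    def of(self, ind_id: str) -> dict:
        return self.records[ind_id]


class _Lineage:
    __slots__ = ("j", "ls", "events", "n_mut")

    def __init__(self, j, ls, events=(), n_mut=0):
        self.j = j
        self.ls = ls
        self.events = events
        self.n_mut = n_mut


def _mutation_bounds(locus: LocusDef, haplome: str) -> tuple[int, int] | None:
    if haplome == "J":
        return locus.j_range if locus.j_range is not None else locus.u_range
    return locus.l_range if locus.l_range is not None else locus.u_range


def simulate(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Run the simulator and return a genotyped Dataset with ground truth."""
    rng = np.random.default_rng(config.seed)
    locus_map = {l.name: l for l in config.loci}
    j_loci = config.j_loci()
    l_loci = config.l_loci()

    # precompute host pool samplers per site
    pool_items: dict[str, dict[str, tuple[list[int], list[float]]]] = {}
    for site, pools in config.host_pools.items():
        pool_items[site] = {
            locus: (sorted(freqs), [freqs[a] for a in sorted(freqs)])
            for locus, freqs in pools.items()
        }

    def host_gamete(site: str) -> dict[str, int]:
        pools = pool_items[site]
        gam = {}
        for locus in l_loci:
            if locus not in pools:
                raise KleptopopError(f"host pool at {site} lacks locus {locus}")
            alleles, probs = pools[locus]
            gam[locus] = int(alleles[rng.choice(len(alleles), p=probs)])
        return gam

    def mutate(hap: dict[str, int], haplome: str) -> tuple[dict[str, int], int]:
        out = None
        n_mut = 0
        for locus_name in hap:
            rate = config.mutation_rate(locus_name)
            if rate <= 0 or rng.random() >= rate:
                continue
            locus = locus_map[locus_name]
            step = locus.motif_length if rng.random() < 0.5 else -locus.motif_length
            allele = hap[locus_name] + step
            bounds = _mutation_bounds(locus, haplome)
            if bounds is not None:
                lo, hi = bounds
                if allele < lo:
                    allele = hap[locus_name] + abs(step)
                elif allele > hi:
                    allele = hap[locus_name] - abs(step)
            if out is None:
                out = dict(hap)
            out[locus_name] = allele
            n_mut += 1
        return (hap if out is None else out), n_mut

    individuals: list[IndividualRecord] = []
    truth: dict[str, dict] = {}

    for grp in config.groups:
        founder_j = {k: grp.founder_j[k] for k in j_loci}
        founder_ls = tuple(
            {k: hap[k] for k in l_loci} for hap in grp.founder_l
        )
        for site in grp.sites:
            pop = [
                _Lineage(founder_j, founder_ls) for _ in range(config.pop_size)
            ]
            has_host = site in pool_items
            for gen in range(config.generations):
                mothers = rng.integers(0, config.pop_size, size=config.pop_size)
                nxt = []
                for m in mothers:
                    mom = pop[m]
                    u = rng.random()
                    ev = None
                    ls = mom.ls
                    if u < grp.exchange_rate and has_host:
                        k = int(rng.integers(0, len(ls)))
                        ls = ls[:k] + (host_gamete(site),) + ls[k + 1 :]
                        ev = ("exchange", gen)
                    elif u < grp.exchange_rate + grp.elevation_rate and has_host:
                        if len(ls) < 3:
                            ls = ls + (host_gamete(site),)
                            ev = ("elevation", gen)
                    elif (
                        u
                        < grp.exchange_rate
                        + grp.elevation_rate
                        + grp.reduction_rate
                    ):
                        if len(ls) > 1:
                            k = int(rng.integers(0, len(ls)))
                            ls = ls[:k] + ls[k + 1 :]
                            ev = ("reduction", gen)
                    j, nm = mutate(mom.j, "J")
                    total_mut = nm
                    new_ls = []
                    for hap in ls:  # mutate returns the same dict if untouched
                        hap, nm = mutate(hap, "L")
                        total_mut += nm
                        new_ls.append(hap)
                    events = mom.events + (ev,) if ev else mom.events
                    nxt.append(
                        _Lineage(j, tuple(new_ls), events, mom.n_mut + total_mut)
                    )
                pop = nxt
            picked = rng.choice(config.pop_size, size=config.n_sampled, replace=False)
            for k, pi in enumerate(sorted(picked)):
                lin = pop[pi]
                ind_id = f"{grp.label}_{site}_{k:02d}"
                genotypes = _genotypes_from_haplomes(
                    lin.j, lin.ls, config.loci, j_loci, l_loci
                )
                individuals.append(
                    IndividualRecord(
                        id=ind_id,
                        site=site,
                        genotypes=genotypes,
                        mtdna_unisexual=True,
                    )
                )
                truth[ind_id] = {
                    "group": grp.label,
                    "biotype": BIOTYPE_BY_L[len(lin.ls)],
                    "events": list(lin.events),
                    "n_mutations": lin.n_mut,
                }

    # sexual host (LL) individuals drawn from the site pools
    for site, n_hosts in config.host_sample.items():
        for k in range(n_hosts):
            hap1, hap2 = host_gamete(site), host_gamete(site)
            ind_id = f"LL_{site}_{k:02d}"
            genotypes = _genotypes_from_haplomes(
                {}, (hap1, hap2), config.loci, j_loci, l_loci
            )
            individuals.append(
                IndividualRecord(
                    id=ind_id, site=site, genotypes=genotypes, mtdna_unisexual=False
                )
            )
            truth[ind_id] = {
                "group": "LL",
                "biotype": "LL",
                "events": [],
                "n_mutations": 0,
            }

    dataset = Dataset(
        individuals=individuals, loci=list(config.loci), sites=config.sites.copy()
    )
    return dataset, SimTruth(records=truth)


def _genotypes_from_haplomes(j, ls, loci, j_loci, l_loci):
    genotypes = {}
    for locus in loci:
        alleles = []
        if locus.name in j and locus.name in j_loci:
            alleles.append(j[locus.name])
        for hap in ls:
            if locus.name in hap:
                alleles.append(hap[locus.name])
        if alleles:
            genotypes[locus.name] = MultisetGenotype(
                locus=locus.name, observed_alleles=tuple(sorted(set(alleles)))
            )
    return genotypes


# ---------------------------------------------------------------------------
# presets


def default_locus_panel() -> list[LocusDef]:
    """The 14-locus panel emulated by all presets: four J-only loci, four
    loci split by disjoint J/L size ranges, and two non-discriminating loci
    whose ranges overlap (excluded from isolocus analyses but genotyped)."""
    return [
        LocusDef("AjeD13", 4, j_range=(200, 240)),
        LocusDef("AjeD294", 4, j_range=(140, 170)),
        LocusDef("AjeD378", 4, j_range=(230, 280)),
        LocusDef("AjeD346", 4, j_range=(154, 186)),
        LocusDef("AmaD42", 4, j_range=(133, 193), l_range=(197, 260)),
        LocusDef("AjeD23", 4, j_range=(173, 197), l_range=(140, 168)),
        LocusDef("AjeD84", 4, j_range=(110, 130), l_range=(84, 106)),
        LocusDef("AjeD422", 4, j_range=(128, 152), l_range=(156, 190)),
        LocusDef("AjeD94", 4, u_range=(100, 146)),
        LocusDef("AjeD283", 4, u_range=(150, 200)),
    ]


CONSENSUS_J = {
    "AjeD13": 208,
    "AjeD294": 150,
    "AjeD378": 240,
    "AjeD346": 162,
    "AmaD42": 133,
    "AjeD23": 181,
    "AjeD84": 120,
    "AjeD422": 140,
    "AjeD94": 110,
    "AjeD283": 155,
}

#: the four multimodal J-loci are mutationally near-frozen in the presets:
#: empirically they show deep allele-size gaps with no intermediate steps,
#: which is only consistent with a much lower effective step rate.
DIAGNOSTIC_MU = 2.5e-5
DIAGNOSTIC_LOCI = ("AmaD42", "AjeD13", "AjeD23", "AjeD378")

FOUNDER_L1 = {
    "AmaD42": 197,
    "AjeD23": 151,
    "AjeD84": 96,
    "AjeD422": 170,
    "AjeD94": 106,
    "AjeD283": 163,
}
FOUNDER_L2 = {
    "AmaD42": 201,
    "AjeD23": 151,
    "AjeD84": 92,
    "AjeD422": 170,
    "AjeD94": 106,
    "AjeD283": 159,
}

#: stationary host allele pools; the divergent alleles (AmaD42 241/253,
#: AjeD94 142) sit 8+ mutation steps from the unisexual founder cluster and
#: segregate at high frequency, as in sympatric sexual populations.
HOST_POOL = {
    "AmaD42": {197: 0.05, 201: 0.10, 205: 0.05, 241: 0.45, 253: 0.35},
    "AjeD23": {147: 0.30, 151: 0.50, 155: 0.20},
    "AjeD84": {92: 0.25, 96: 0.55, 100: 0.20},
    "AjeD422": {166: 0.30, 170: 0.45, 174: 0.25},
    "AjeD94": {102: 0.10, 106: 0.12, 142: 0.78},
    "AjeD283": {159: 0.40, 163: 0.40, 167: 0.20},
}


def default_rule_table() -> DiagnosticRuleTable:
    """Five-group assignment rules over the four multimodal J-isoloci."""
    return DiagnosticRuleTable(
        consensus={
            "AmaD42-J": (133,),
            "AjeD13-J": (208,),
            "AjeD23-J": (181,),
            "AjeD378-J": (240,),
        },
        diagnostics={
            "A": (("AmaD42-J", 137),),
            "C": (("AjeD13-J", 224), ("AjeD23-J", 197)),
            "D": (("AjeD378-J", 264),),
            "E": (("AmaD42-J", 193),),
        },
        consensus_group="B",
    )


def _founder_j(diagnostics: dict[str, int] | None = None) -> dict[str, int]:
    j = dict(CONSENSUS_J)
    if diagnostics:
        j.update(diagnostics)
    return j


def _sites(labels_coords) -> pd.DataFrame:
    return pd.DataFrame(
        labels_coords, columns=["site", "latitude", "longitude"]
    )


EXCHANGE_RATES = dict(exchange_rate=0.15, elevation_rate=0.02, reduction_rate=0.02)


def preset(name: str, seed: int = 0) -> SimConfig:
    """Named study conditions.

    - ``clonal_only``: one strictly clonal triploid group (A) across three
      isolated sites, no hosts — the among-site-mutation signature.
    - ``all_diploid``: a diploid clonal group (D) at two sites with no
      compatible sperm donor, as in the all-diploid eastern ponds.
    - ``exchange_only``: one exchanging triploid group (B) at two sites with
      sexual LL hosts carrying highly divergent alleles.
    - ``mixed_sympatry``: clonal group A sympatric with exchanging groups B
      and E plus sexual hosts — the discriminating design of the main site.
    """
    loci = default_locus_panel()
    mu_over = {l: DIAGNOSTIC_MU for l in DIAGNOSTIC_LOCI}
    if name == "clonal_only":
        return SimConfig(
            loci=loci,
            sites=_sites(
                [("S1", 45.40, -73.95), ("S2", 45.50, -73.75), ("S3", 45.68, -73.51)]
            ),
            groups=[
                GroupSpec(
                    "A",
                    _founder_j({"AmaD42": 137}),
                    (FOUNDER_L1, FOUNDER_L2),
                    ("S1", "S2", "S3"),
                )
            ],
            mu_overrides=mu_over,
            seed=seed,
        )
    if name == "all_diploid":
        return SimConfig(
            loci=loci,
            sites=_sites([("E01", 45.55, -73.17), ("E02", 45.43, -72.63)]),
            groups=[
                GroupSpec(
                    "D",
                    _founder_j({"AjeD378": 264}),
                    (FOUNDER_L1,),
                    ("E01", "E02"),
                )
            ],
            mu_overrides=mu_over,
            seed=seed,
        )
    if name == "exchange_only":
        sites = ("S1", "S2")
        return SimConfig(
            loci=loci,
            sites=_sites([("S1", 45.40, -73.95), ("S2", 45.50, -73.75)]),
            groups=[
                GroupSpec(
                    "B",
                    _founder_j(),
                    (FOUNDER_L1, FOUNDER_L2),
                    sites,
                    **EXCHANGE_RATES,
                )
            ],
            host_pools={s: HOST_POOL for s in sites},
            host_sample={s: 8 for s in sites},
            mu_overrides=mu_over,
            seed=seed,
        )
    if name == "mixed_sympatry":
        return SimConfig(
            loci=loci,
            sites=_sites(
                [("S1", 45.43, -73.95), ("S2", 45.50, -73.78), ("S3", 45.68, -73.51)]
            ),
            groups=[
                GroupSpec(
                    "A",
                    _founder_j({"AmaD42": 137}),
                    (FOUNDER_L1, FOUNDER_L2),
                    ("S1", "S2", "S3"),
                ),
                GroupSpec(
                    "B",
                    _founder_j(),
                    (FOUNDER_L1, FOUNDER_L2),
                    ("S1", "S2"),
                    **EXCHANGE_RATES,
                ),
                GroupSpec(
                    "E",
                    _founder_j({"AmaD42": 193}),
                    (FOUNDER_L1, FOUNDER_L2),
                    ("S1", "S3"),
                    **EXCHANGE_RATES,
                ),
            ],
            host_pools={s: HOST_POOL for s in ("S1", "S2", "S3")},
            host_sample={s: 7 for s in ("S1", "S2", "S3")},
            mu_overrides=mu_over,
            seed=seed,
        )
    raise KleptopopError(f"unknown preset {name!r}")


def aflp_from_dataset(dataset: Dataset, min_freq: float = 0.0) -> "AflpMatrix":
    """Derive a dominant-marker (AFLP-like) matrix from genotypes.

    Every (locus, allele) pair observed in the dataset becomes one band;
    an individual shows the band iff it carries the allele.  This mirrors
    how dominant AFLP bands track underlying sequence variants.  Bands fixed
    across all individuals are dropped (uninformative), as are bands rarer
    than ``min_freq``.
    """
    from .model import AflpMatrix

    ids = [ind.id for ind in dataset.individuals]
    bands: dict[str, list[int]] = {}
    for locus in dataset.loci:
        alleles = sorted(
            {
                a
                for ind in dataset.individuals
                for a in ind.genotypes.get(locus.name, MultisetGenotype(locus.name)).observed_alleles
            }
        )
        for a in alleles:
            col = [
                int(
                    locus.name in ind.genotypes
                    and a in ind.genotypes[locus.name].observed_alleles
                )
                for ind in dataset.individuals
            ]
            freq = sum(col) / len(col)
            if 0 < freq < 1 and freq >= min_freq:
                bands[f"{locus.name}_{a}"] = col
    names = sorted(bands)
    matrix = np.array([bands[b] for b in names]).T if names else np.zeros((len(ids), 0))
    return AflpMatrix(individuals=ids, bands=names, presence=matrix)
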