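"""Synthetic data with known truth, and the worked example dataset.

Two generators live here.

:func:`simulate_scenario` draws genotypes under the Balding–Nichols
construction — an ancestral frequency p0 ~ Uniform(0.05, 0.95) per
site and pool frequencies p ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) for a
drift/divergence parameter F — with diploid dosages
Binomial(2, sum_k q_ik p_kj) under each taxon's planted ancestry
vector, per-population trait values, and a plastid (maternal-pool)
clade map that can encode capture events discordant with nuclear
ancestry. Every planted quantity is recorded in a truth table.

:func:`buxifolius_complex_fixture` is a SYNTHETIC, hand-curated
encoding of the published structure of the Cotoneaster buxifolius
species complex (29 sampled taxa, 43 populations, nine gene pools at
K=9): which taxa are single-pool, which are admixed and from which
pools, the nuclear/plastid backbone-clade placements, and the K=19
pool sharing. Ancestry magnitudes (0.97 for single-pool taxa, 0.72
for the near-pure exception, 0.60 dominant shares for admixed taxa)
are stand-ins constrained only by the documented inequalities
(pure > 0.95, the exception in (0.70, 0.95), admixed < 0.70); every
downstream count is invariant to jitter within those bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import ADMIXED, PURE, SUBTHRESHOLD, PurityCall
from .datatypes import (INFRASPECIFIC, SPECIES, AncestryMatrix, CladeMap,
                        GenotypeMatrix, SampleMap, Site, Trait, TraitTable,
                        QUALITATIVE, QUANTITATIVE)
from .delimit import DelimitConfig, DelimitationReport, run_delimitation
from .phylo import bootstrap_supports
from .trees import SupportTree, parse_support_tree

HYBRID_TRUTH = "HYBRID"
VALID_TRUTH = "VALID"


# ---------------------------------------------------------------------
# scenario simulation

@dataclass
class TaxonSpec:
    """Planted per-taxon truth for one synthetic taxon."""

    name: str
    q: tuple[float, ...]
    rank: str = SPECIES
    n_populations: int = 1
    samples_per_population: int = 8
    maternal_pool: int | None = None
    quant_means: tuple[float, ...] = ()
    qual_states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.q) - 1.0) > 1e-9:
            raise ValueError(f"true q of {self.name!r} does not sum to 1")
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("nonpositive population/sample counts")


@dataclass
class Scenario:
    """Full specification of one synthetic study."""

    n_pools: int
    divergence: float
    taxa: list[TaxonSpec]
    n_sites: int = 1000
    trait_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence F must be in (0, 1)")
        for t in self.taxa:
            if len(t.q) != self.n_pools:
                raise ValueError(f"q of {t.name!r} has wrong length")
            if t.maternal_pool is not None and \
                    not 0 <= t.maternal_pool < self.n_pools:
                raise ValueError(
                    f"maternal pool of {t.name!r} references no pool")


@dataclass
class SimulatedData:
    genotypes: GenotypeMatrix
    sample_map: SampleMap
    traits: TraitTable
    plastid_clades: CladeMap
    pool_frequencies: np.ndarray
    truth: pd.DataFrame  # per taxon: true q columns, status, maternal pool


def simulate_scenario(S: Scenario) -> SimulatedData:
    """Draw a full synthetic dataset; deterministic under ``S.seed``."""
    rng = np.random.default_rng(S.seed)
    K, L = S.n_pools, S.n_sites
    F = S.divergence
    p0 = rng.uniform(0.05, 0.95, size=L)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    pools = rng.beta(a, b, size=(K, L))
    pools = np.clip(pools, 1e-4, 1.0 - 1e-4)

    samples, rows, map_rows = [], [], []
    trait_rows, trait_idx = [], []
    plastid: dict[str, str] = {}
    truth_rows = []
    n_quant = len(S.taxa[0].quant_means) if S.taxa else 0
    for spec in S.taxa:
        qvec = np.asarray(spec.q)
        site_p = qvec @ pools
        maternal = (spec.maternal_pool if spec.maternal_pool is not None
                    else int(np.argmax(qvec)))
        pure = np.max(qvec) > 0.999
        for ip in range(spec.n_populations):
            pop = f"{spec.name}_p{ip + 1}"
            plastid[pop] = f"P{maternal}"
            quant = [rng.normal(m, S.trait_sd) for m in spec.quant_means]
            trait_rows.append(list(quant) + list(spec.qual_states))
            trait_idx.append(pop)
            for js in range(spec.samples_per_population):
                sid = f"{pop}_s{js + 1}"
                samples.append(sid)
                rows.append(rng.binomial(2, site_p))
                map_rows.append((sid, pop, spec.name, spec.rank))
        truth_rows.append([spec.name,
                           VALID_TRUTH if pure else HYBRID_TRUTH,
                           maternal] + list(qvec))
    dosages = np.asarray(rows, dtype=np.int16)
    sites = [Site("chr1", j + 1) for j in range(L)]
    G = GenotypeMatrix(samples, sites, dosages)
    M = SampleMap.from_records(map_rows)
    schema = ([Trait(f"quant{i + 1}", QUANTITATIVE, unit="mm")
               for i in range(n_quant)]
              + [Trait(f"qual{i + 1}", QUALITATIVE)
                 for i in range(len(S.taxa[0].qual_states))])
    values = pd.DataFrame(trait_rows, index=trait_idx,
                          columns=[t.name for t in schema])
    traits = TraitTable(values, schema)
    truth = pd.DataFrame(
        truth_rows,
        columns=["taxon", "status", "maternal_pool"]
        + [f"q{k}" for k in range(K)]).set_index("taxon")
    return SimulatedData(G, M, traits, CladeMap(plastid), pools, truth)


def make_scenario(n_pools: int, n_hybrids: int = 0, seed: int = 0,
                  divergence: float = 0.2, n_sites: int = 2000,
                  n_populations: int = 2, samples_per_population: int = 5,
                  effect_sd: float = 4.0,
                  hybrid_fractions: tuple[float, float] = (0.6, 0.4)
                  ) -> Scenario:
    """Standard study-condition scenario: one pure taxon per pool plus
    planted hybrids.

    Each pure taxon owns one pool, two quantitative traits separated by
    ``effect_sd`` within-taxon standard deviations, and two taxon-
    diagnostic qualitative states. Hybrids mix two parental pools
    (major/minor per ``hybrid_fractions``), inherit the major parent's
    quantitative means and one qualitative state from each parent
    (morphological intermediacy), and carry the *minor* parent's
    plastid — so cytonuclear discordance is an emergent signal, not an
    annotation.
    """
    if n_hybrids > n_pools // 2:
        raise ValueError("need two distinct parents per hybrid")
    taxa = []
    for k in range(n_pools):
        q = tuple(1.0 if i == k else 0.0 for i in range(n_pools))
        taxa.append(TaxonSpec(
            name=f"taxon{k}", q=q, n_populations=n_populations,
            samples_per_population=samples_per_population,
            quant_means=(k * effect_sd, -k * effect_sd),
            qual_states=(2 * k, 2 * k + 1)))
    hi, lo = hybrid_fractions
    for h in range(n_hybrids):
        pa, pb = 2 * h, 2 * h + 1
        q = [0.0] * n_pools
        q[pa], q[pb] = hi, lo
        taxa.append(TaxonSpec(
            name=f"hybrid{h}", q=tuple(q), n_populations=n_populations,
            samples_per_population=samples_per_population,
            maternal_pool=pb,
            quant_means=(pa * effect_sd, -pa * effect_sd),
            qual_states=(2 * pa, 2 * pb + 1)))
    return Scenario(n_pools=n_pools, divergence=divergence, taxa=taxa,
                    n_sites=n_sites, seed=seed)


def delimit_scenario(sim: SimulatedData, K: int, seed: int = 0,
                     n_boot: int = 100, em_max_iter: int = 300,
                     config: DelimitConfig | None = None
                     ) -> DelimitationReport:
    """Run the full pipeline (EM -> tree+bootstrap -> cascade) on a
    simulated dataset."""
    from .ancestry import AdmixtureModel

    res = AdmixtureModel(sim.genotypes, K).fit(seed=seed,
                                               max_iter=em_max_iter)
    tree = bootstrap_supports(sim.genotypes, n_reps=n_boot, seed=seed + 1)
    seeds: dict[str, set] = {}
    for taxon, row in sim.truth.iterrows():
        if row["status"] != VALID_TRUTH:
            continue
        pool = int(np.argmax(row[[c for c in sim.truth.columns
                                  if c.startswith("q")]].to_numpy()))
        tips = sim.sample_map.samples_of_taxon(taxon)[:2]
        seeds.setdefault(f"N{pool}", set()).update(tips)
    return run_delimitation(res.Q, sim.sample_map, sim.traits,
                            config=config, nuclear_tree=tree,
                            nuclear_clade_seeds=seeds,
                            plastid_clades=sim.plastid_clades)


# ---------------------------------------------------------------------
# the Cotoneaster buxifolius complex fixture

NA, NB, NC = "NA", "NB", "NC"
PA, PB, PC = "PA", "PB", "PC"

_PURE = 0.97       # synthetic stand-in for "> 0.95 single-cluster"
_NEAR = 0.72       # synthetic stand-in for the "> 0.70" exception
_ADM = 0.60        # synthetic stand-in for admixed dominant shares

# (name, rank, series, n_pops, nuclear clade, plastid clade per pop,
#  dominant pool, dominant share, minor pools {pool: share},
#  K=19 pool, still-admixed at K=19, backbone clade on the hybrid-free
#  rebuilt tree or None for taxa dropped from it)
_TAXA: list[tuple] = [
    ("C_conspicuus", SPECIES, "C", 1, NA, [PC], 0, _PURE, {}, 0, False, NA),
    ("C_sherriffii", SPECIES, "C", 1, NA, [PA], 0, _PURE, {}, 0, False, NA),
    ("C_microphyllus", SPECIES, "M", 1, NA, [PA], 0, _PURE, {}, 9, False,
     NA),
    ("C_rockii", SPECIES, "B", 1, NA, [PC], 1, _PURE, {}, 10, False, NC),
    ("C_sp1", SPECIES, "B", 1, NA, [PC], 1, _PURE, {}, 11, True, NC),
    ("C_insolitus", SPECIES, "B", 1, NA, [PC], 1, _ADM,
     {0: 0.2, 5: 0.2}, 1, True, None),
    ("C_buxifolius_var_vellaeus", INFRASPECIFIC, "B", 1, NA, [PA], 1, _ADM,
     {0: 0.2, 6: 0.2}, 1, True, None),
    ("C_marginatus", SPECIES, "M", 1, NA, [PB], 1, _ADM,
     {0: 0.4 / 3, 2: 0.4 / 3, 5: 0.4 / 3}, 1, True, None),
    ("C_buxifolius", SPECIES, "B", 2, NB, [PC, PC], 5, _ADM, {6: 0.4},
     17, False, None),
    ("C_lidjiangensis", SPECIES, "B", 1, NB, [PC], 5, _ADM, {6: 0.4},
     17, False, None),
    ("C_argenteus", SPECIES, "B", 2, NB, [PC, PC], 3, _ADM, {6: 0.4},
     14, False, None),
    ("C_glaucophyllus", SPECIES, "P", 1, NB, [PB], 3, _PURE, {}, 3, False,
     NB),
    ("C_meiophyllus", SPECIES, "P", 4, NB, [PB] * 4, 3, _ADM, {5: 0.4},
     13, False, None),
    ("C_serotinus", SPECIES, "P", 1, NB, [PC], 4, _PURE, {}, 4, False, NC),
    ("C_sp2", SPECIES, "S", 1, NB, [PC], 4, _ADM, {2: 0.2, 8: 0.2},
     4, False, None),
    ("C_cochleatus", SPECIES, "R", 1, NB, [PA], 0, _ADM, {3: 0.4},
     18, False, None),
    ("C_dammeri", SPECIES, "R", 1, NB, [PA], 3, _PURE, {}, 16, False, NB),
    ("C_dammeri_subsp_songmingensis", INFRASPECIFIC, "R", 1, NB, [PB], 3,
     _PURE, {}, 16, False, NB),
    ("C_morrisonensis", SPECIES, "R", 1, NB, [PB], 2, _ADM,
     {0: 0.2, 3: 0.2}, 18, False, None),
    ("C_salicifolius", SPECIES, "S", 1, NB, [PB], 2, _PURE, {}, 12, False,
     NB),
    ("C_brickellii", SPECIES, "P", 1, NC, [PB], 7, _PURE, {}, 7, False, NC),
    ("C_pannosus", SPECIES, "P", 2, NC, [PB, PC], 6, _ADM, {7: 0.4},
     6, True, None),
    ("C_turbinatus", SPECIES, "P", 3, NC, [PC] * 3, 8, _PURE, {}, 8, False,
     NC),
    ("C_coriaceus", SPECIES, "P", 2, NC, [PC] * 2, 8, _PURE, {}, 15, False,
     NC),
    ("C_lacteus", SPECIES, "P", 4, NC, [PC] * 4, 8, _ADM,
     {6: 0.4 / 3, 2: 0.4 / 3, 3: 0.4 / 3}, 8, True, None),
    ("C_fulvidus", SPECIES, "P", 2, NC, [PC] * 2, 5, _NEAR, {4: 0.28},
     5, False, NC),
    ("C_delavayanus", SPECIES, "B", 2, NC, [PC] * 2, 6, _PURE, {}, 6, False,
     NC),
    ("C_sp3", SPECIES, "M", 1, NC, [PB], 7, _ADM, {2: 0.2, 6: 0.2},
     1, False, None),
    ("C_sp4", SPECIES, "P", 1, NC, [PB], 7, _ADM, {3: 0.2, 2: 0.2},
     2, False, None),
]

K9 = 9
K19 = 19

# taxa whose qualitative state is shared with a putative parent so the
# cascade can see morphological intermediacy (documented hybrid cases)
_INTERMEDIATE_WITH = {
    "C_marginatus": "C_rockii",
    "C_insolitus": "C_conspicuus",
    "C_buxifolius_var_vellaeus": "C_rockii",
    "C_cochleatus": "C_microphyllus",
    "C_morrisonensis": "C_dammeri",
}
# taxa indistinguishable from a partner (shared trait states)
_TRAIT_TWINS = {
    "C_dammeri_subsp_songmingensis": "C_dammeri",
    "C_lidjiangensis": "C_buxifolius",
}


@dataclass
class BuxifoliusFixture:
    """Everything the worked example and the acceptance checks consume."""

    sample_map: SampleMap
    ancestry_k9: AncestryMatrix
    calls_k19: list[PurityCall]
    nuclear_clades: CladeMap
    plastid_clades: CladeMap
    rebuilt_nuclear_clades: CladeMap
    traits: TraitTable
    nuclear_tree: SupportTree
    taxa: list[str] = field(default_factory=list)


def _q_vector(dom: int, share: float, minors: dict[int, float],
              jitter: float) -> np.ndarray:
    q = np.zeros(K9)
    share = share + jitter
    q[dom] = share
    rest = 1.0 - share
    base_rest = sum(minors.values())
    if minors:
        scale = (rest if base_rest > 0 else 0.0)
        for pool, frac in minors.items():
            q[pool] = frac / base_rest * scale
    leftover = 1.0 - q.sum()
    if leftover > 1e-12:
        others = [k for k in range(K9) if k != dom and k not in minors]
        for k in others:
            q[k] = leftover / len(others)
    return q / q.sum()


def buxifolius_complex_fixture(dominant_jitter: float = 0.0
                               ) -> BuxifoliusFixture:
    """Build the synthetic worked-example dataset for the complex.

    ``dominant_jitter`` shifts every dominant ancestry share by up to
    +/- 0.02 (minor shares rescaled proportionally); all summary counts
    are invariant to it because the encoded magnitudes sit strictly
    inside the documented inequality bounds.
    """
    if abs(dominant_jitter) > 0.02 + 1e-12:
        raise ValueError("jitter must stay within +/- 0.02")
    map_rows, q_rows, q_samples = [], [], []
    nuclear, plastid, rebuilt = {}, {}, {}
    calls_k19: list[PurityCall] = []
    taxa = []
    for (name, rank, series, npops, nuc, pla, dom, share, minors,
         k19pool, k19adm, rebuilt_clade) in _TAXA:
        taxa.append(name)
        qvec = _q_vector(dom, share, minors, dominant_jitter)
        for ip in range(npops):
            pop = f"{name}_p{ip + 1}"
            nuclear[pop] = nuc
            plastid[pop] = pla[ip]
            if rebuilt_clade is not None:
                rebuilt[pop] = rebuilt_clade
            for js in range(2):
                sid = f"{pop}_s{js + 1}"
                map_rows.append((sid, pop, name, rank, series))
                q_samples.append(sid)
                q_rows.append(qvec)
        k19_share = (_ADM if k19adm else _PURE) + dominant_jitter
        calls_k19.append(PurityCall(
            name, k19pool, k19_share,
            ADMIXED if k19adm else PURE,
            [k19pool]))
    M = SampleMap.from_records(map_rows)
    Q9 = AncestryMatrix(q_samples, np.asarray(q_rows),
                        meta={"K": K9, "source": "fixture"})
    traits = _fixture_traits(taxa)
    tree = _fixture_tree()
    return BuxifoliusFixture(M, Q9, calls_k19, CladeMap(nuclear),
                             CladeMap(plastid), CladeMap(rebuilt),
                             traits, tree, taxa)


def _fixture_traits(taxa: list[str]) -> TraitTable:
    """Two qualitative traits; unique state pair per taxon except the
    documented indistinguishable pairs and the planted intermediates."""
    state_a = {t: 2 * i for i, t in enumerate(taxa)}
    state_b = {t: 2 * i + 1 for i, t in enumerate(taxa)}
    for t, twin in _TRAIT_TWINS.items():
        state_a[t] = state_a[twin]
        state_b[t] = state_b[twin]
    for t, parent in _INTERMEDIATE_WITH.items():
        state_a[t] = state_a[parent]
    schema = [Trait("leaf_indumentum", QUALITATIVE),
              Trait("fruit_form", QUALITATIVE)]
    values = pd.DataFrame(
        {"leaf_indumentum": [state_a[t] for t in taxa],
         "fruit_form": [state_b[t] for t in taxa]},
        index=taxa)
    return TraitTable(values.astype(float), schema)


def _fixture_tree() -> SupportTree:
    """Population-level nuclear tree: three backbone clades, each taxon
    monophyletic with high stem support, except the documented
    non-monophyletic two-population taxon in clade NC."""
    sup = "99.9/100"
    by_clade: dict[str, list[str]] = {NA: [], NB: [], NC: []}
    for (name, _rank, _series, npops, nuc, *_rest) in _TAXA:
        pops = [f"{name}_p{i + 1}" for i in range(npops)]
        if name == "C_pannosus":
            # populations placed apart: taxon not monophyletic
            by_clade[nuc].extend(pops)
        elif npops == 1:
            by_clade[nuc].append(pops[0])
        else:
            by_clade[nuc].append("(" + ",".join(pops) + ")" + sup)
    blocks = ["(" + ",".join(by_clade[c]) + ")" + sup for c in (NA, NB, NC)]
    newick = "(" + ",".join(blocks) + ");"
    return parse_support_tree(newick)
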