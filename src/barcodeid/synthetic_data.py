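"""Synthetic barcoding scenarios with known ground truth.

Everything the identification pipeline consumes can be generated here with
full determinism: species trees, reference databases evolved under a
parameterized substitution model, intraspecific variation, query barcodes,
Sanger-style read pairs with declining quality, deliberately mislabeled
reference lineages (emulating database confusion), out-of-database species
(emulating undescribed taxa), and conservation-status tables.

Defaults emulate the statistical structure of a curated elasmobranch COI
reference set: ~650 bp coding sequences under HKY+G+I, interspecific ML
distances of roughly 0.5-15%, intraspecific distances below 1%, and 2-8
reference sequences per species. Intraspecific variation uses a star
genealogy, which keeps the truth analytic; generated coding sequences are
kept free of in-frame stop codons so that Numt screening passes by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conservation import ConservationStatusTable
from .models_distance import HKY_COI_DEFAULT, SubstitutionModel, _tn93_probs
from .refsearch import ReferenceDB, TaxonRef
from .seqio_qc import ConsensusRecord, QualityRead
from .tree_support import PhyloTree, _Node

__all__ = [
    "SimScenario",
    "MarketConfig",
    "sim_species_tree",
    "sim_alignment",
    "sim_read_pair",
    "sim_market_scenario",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# stop codons of the vertebrate mitochondrial code (NCBI table 2)
_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def sim_species_tree(n_species: int, birth_rate: float = 10.0, seed: int = 0,
                     labels=None, target_mean_distance: float | None = None) -> PhyloTree:
    """Pure-birth (Yule) species tree.

    Starting from two lineages, each interval with k lineages lasts
    Exp(k * birth_rate); a final hanging interval with n lineages places the
    tips at the present, so the expected root-to-tip depth is
    ``sum_{k=2..n} 1/(k*birth_rate)``. If ``target_mean_distance`` is given,
    branch lengths are rescaled so the mean pairwise tip distance matches it
    (default tuning aims interspecific barcode distances at the 1-15% scale).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    labels = list(labels) if labels is not None else \
        [f"Species{i + 1:03d}" for i in range(n_species)]
    if len(labels) != n_species:
        raise ValueError("label count != n_species")

    root = _Node()
    a, b = _Node(), _Node()
    root.children = [a, b]
    tips = [a, b]

    k = 2
    while k < n_species:
        t = rng.exponential(1.0 / (k * birth_rate))
        for tip in tips:
            tip.edge_length += t
        split = tips[rng.integers(len(tips))]
        c1, c2 = _Node(), _Node()
        split.children = [c1, c2]
        tips.remove(split)
        tips.extend([c1, c2])
        k += 1
    t = rng.exponential(1.0 / (n_species * birth_rate))
    for tip in tips:
        tip.edge_length += t

    order = rng.permutation(n_species)
    for tip, lab_idx in zip(tips, order):
        tip.label = labels[lab_idx]
    tree = PhyloTree(root)

    if target_mean_distance is not None:
        labs = sorted(tree.leaf_labels)
        dists = [tree.path_distance(x, y) for i, x in enumerate(labs)
                 for y in labs[i + 1:]]
        scale = target_mean_distance / np.mean(dists)
        _scale_tree(tree, scale)
    return tree


def _scale_tree(tree: PhyloTree, factor: float) -> None:
    stack = [tree.root]
    while stack:
        n = stack.pop()
        n.edge_length *= factor
        stack.extend(n.children)


def _draw_site_classes(model: SubstitutionModel, n_sites: int, rng):
    """Per-site invariant flag and gamma-category rate, fixed down the tree."""
    invariant = rng.random(n_sites) < model.p_inv
    cats = rng.integers(0, model.ncat, size=n_sites)
    rates = model.category_rates[cats]
    rates[invariant] = 0.0
    return rates


def _root_sequence(model: SubstitutionModel, n_sites: int, rng,
                   coding: bool = True) -> np.ndarray:
    """Stationary-frequency sequence, stop-free in frame 0 when coding."""
    freqs = model.freqs
    seq = rng.choice(4, size=n_sites, p=freqs)
    if coding:
        _scrub_stops(seq, None, rng, freqs)
    return seq


def _scrub_stops(seq: np.ndarray, template: np.ndarray | None, rng, freqs) -> None:
    """Replace any frame-0 mitochondrial stop codon in place.

    With a template (the ancestral sequence, itself stop-free) the offending
    codon reverts to the template codon; without one, it is redrawn.
    """
    n_codons = len(seq) // 3
    view = seq[: n_codons * 3].reshape(n_codons, 3)
    for c in range(n_codons):
        codon = "".join(_BASES[view[c]])
        if codon in _MITO_STOPS:
            if template is not None:
                view[c] = template[c * 3:(c + 1) * 3]
            else:
                while codon in _MITO_STOPS:
                    view[c] = rng.choice(4, size=3, p=freqs)
                    codon = "".join(_BASES[view[c]])


def _evolve(seq: np.ndarray, t: float, site_rates: np.ndarray,
            model: SubstitutionModel, rng, coding: bool = True) -> np.ndarray:
    """Evolve a sequence along a branch of length t (subst/site)."""
    child = seq.copy()
    if t <= 0:
        return child
    for rate in np.unique(site_rates):
        if rate == 0.0:
            continue
        idx = np.where(site_rates == rate)[0]
        P = _tn93_probs(model.freqs, model.kappa, t * rate)
        probs = P[child[idx]]  # (n_idx, 4)
        u = rng.random(len(idx))
        child[idx] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    if coding:
        _scrub_stops(child, seq, rng, model.freqs)
    return child


def _evolve_tree(tree: PhyloTree, model: SubstitutionModel, n_sites: int, rng,
                 coding: bool = True):
    """Sequences at every leaf, plus the shared site-rate vector."""
    site_rates = _draw_site_classes(model, n_sites, rng)
    root_seq = _root_sequence(model, n_sites, rng, coding=coding)
    leaf_seqs = {}

    def walk(node, seq):
        for ch in node.children:
            child_seq = _evolve(seq, ch.edge_length, site_rates, model, rng,
                                coding=coding)
            if ch.is_leaf:
                leaf_seqs[ch.label] = child_seq
            else:
                walk(ch, child_seq)

    walk(tree.root, root_seq)
    return leaf_seqs, site_rates


def sim_alignment(tree: PhyloTree, model: SubstitutionModel = HKY_COI_DEFAULT,
                  n_sites: int = 650, n_per_species=(2, 8),
                  intra_divergence: float = 0.005, seed: int = 0,
                  genus_map: dict | None = None, coding: bool = True,
                  return_truth: bool = False):
    """Reference database evolved down a species tree.

    Each species' barcode evolves from the root along the tree; conspecific
    reference sequences then radiate on a star genealogy of pendant length
    ``intra_divergence / 2`` (so typical conspecific pairs sit at
    ``intra_divergence``). ``genus_map`` assigns species to genera (default:
    one genus per species, keyed by the species label's first token).

    With ``coding=True`` (the default) in-frame mitochondrial stop codons
    are purged as they arise, so the output always passes Numt screening;
    this purifying constraint slightly biases base composition away from
    the model's stationary frequencies, so substitution-model recovery
    experiments should set ``coding=False`` to sample exactly from the
    stated model.
    """
    rng = np.random.default_rng(seed)
    leaf_seqs, site_rates = _evolve_tree(tree, model, n_sites, rng,
                                         coding=coding)
    lo, hi = (n_per_species, n_per_species) if isinstance(n_per_species, int) \
        else n_per_species
    records = []
    acc = 0
    for species in sorted(leaf_seqs):
        genus = genus_map[species] if genus_map else species.split()[0]
        n_refs = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        for _ in range(n_refs):
            acc += 1
            ref_seq = _evolve(leaf_seqs[species], intra_divergence / 2.0,
                              site_rates, model, rng, coding=coding)
            records.append(TaxonRef(
                accession=f"SIM{acc:05d}", species=species, genus=genus,
                aligned_seq=_decode(ref_seq)))
    db = ReferenceDB(records)
    if return_truth:
        return db, leaf_seqs, site_rates
    return db


def sim_read_pair(template: str, mean_q: int = 40, q_decay: float = 0.02,
                  read_frac: float = 0.65, errors: bool = True,
                  seed: int = 0, read_id: str = "read"):
    """Simulate a Sanger-style forward/reverse read pair from a template.

    The forward read covers the 5' region and the reverse read (delivered
    reverse-complemented, as sequenced) the 3' region; each covers
    ``read_frac`` of the template so the pair overlaps in the middle.
    Quality declines linearly along each read at ``q_decay`` per base;
    bases miscall with probability ``10**(-q/10)`` when ``errors`` is on.
    """
    if len(template) < 100:
        raise ValueError("template must be at least 100 bases")
    rng = np.random.default_rng(seed)
    L = len(template)
    rlen = max(int(round(read_frac * L)), 100)

    def make(sub: str, rid: str, orientation: str):
        quals = np.maximum(2, np.round(mean_q - q_decay * np.arange(len(sub)))).astype(int)
        bases = list(sub)
        if errors:
            p_err = 10.0 ** (-quals / 10.0)
            miscall = rng.random(len(sub)) < p_err
            for i in np.where(miscall)[0]:
                others = [b for b in "ACGT" if b != bases[i]]
                bases[i] = others[rng.integers(3)]
        return QualityRead(read_id=rid, bases="".join(bases),
                           quals=list(quals), orientation=orientation)

    fwd = make(template[:rlen], f"{read_id}/1", "forward")
    rev_region = template[L - rlen:]
    rev_seq = "".join(_COMP[b] for b in reversed(rev_region))
    rev = make(rev_seq, f"{read_id}/2", "reverse")
    return fwd, rev


@dataclass
class MarketConfig:
    """Study design of a simulated market-sampling scenario."""

    n_species: int = 15
    n_genera: int = 5
    n_sites: int = 650
    refs_per_species: tuple = (2, 8)
    intra_divergence: float = 0.005
    genus_mean_distance: float = 0.08   # mean interspecific distance within a genus
    min_interspecific: float = 0.05     # floor on any species-pair separation
    between_genus_distance: float = 0.18
    n_queries: int = 60
    query_skew: float = 0.5             # geometric decay of per-species sampling
    frac_out_of_db: float = 0.0         # fraction of queries from withheld species
    n_mislabeled_lineages: int = 0
    as_read_pairs: bool = False
    status_probs: dict = field(default_factory=lambda: {
        "CR": 0.15, "EN": 0.15, "VU": 0.2, "NT": 0.15, "LC": 0.2, "DD": 0.15})
    model: SubstitutionModel = HKY_COI_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_out_of_db <= 1.0):
            raise ValueError("frac_out_of_db must be in [0, 1]")
        if abs(sum(self.status_probs.values()) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")
        if self.n_genera > self.n_species:
            raise ValueError("more genera than species")


@dataclass
class SimScenario:
    """A fully self-consistent simulated study with its truth table."""

    config: MarketConfig
    true_tree: PhyloTree
    model: SubstitutionModel
    refdb: ReferenceDB
    queries: list                 # (ConsensusRecord | (fwd, rev), true_species)
    label_map: dict               # sample_id -> market label
    status_table: ConservationStatusTable
    group_map: dict               # species -> taxonomic group
    mislabeled: list              # (victim_species, wrong_label_species)
    out_of_db: list               # species withheld from refdb
    seed: int


def _genus_partition(n_species: int, n_genera: int):
    sizes = [n_species // n_genera] * n_genera
    for i in range(n_species % n_genera):
        sizes[i] += 1
    return sizes


def sim_market_scenario(config: MarketConfig | None = None) -> SimScenario:
    """Generate a market-survey scenario: references, queries, statuses.

    The species tree is two-level: genera hang off a central polytomy at
    ``between_genus_distance / 2`` each, and species radiate within each
    genus on a Yule subtree scaled to ``genus_mean_distance``. Queries are
    drawn with a geometric skew over species (a few dominant species, a
    long tail, as market surveys find). Optional features: out-of-database
    species (their references are withheld; their queries model undescribed
    taxa), and mislabeled reference lineages (an extra reference generated
    at a victim species' star center but labeled with a congener's name,
    emulating database confusion).
    """
    config = config or MarketConfig()
    rng = np.random.default_rng(config.seed)
    sizes = _genus_partition(config.n_species, config.n_genera)

    # two-level species tree: central polytomy of genus subtrees
    root = _Node()
    genus_map = {}
    genus_names = [f"Genus{i + 1:02d}" for i in range(config.n_genera)]
    species_names = []
    for g, (gname, size) in enumerate(zip(genus_names, sizes)):
        labels = [f"{gname} sp{j + 1:02d}" for j in range(size)]
        for lab in labels:
            genus_map[lab] = gname
        species_names.extend(labels)
        if size == 1:
            node = _Node(labels[0])
            node.edge_length = config.between_genus_distance / 2.0
            root.children.append(node)
            continue
        sub = sim_species_tree(size, seed=int(rng.integers(2**31)),
                               labels=labels,
                               target_mean_distance=config.genus_mean_distance)
        # a Yule subtree scaled to a target mean can still hold near-zero
        # sister splits; pad pendant edges so every species pair is at
        # least min_interspecific apart
        min_pair = min(sub.path_distance(a, b)
                       for i, a in enumerate(labels) for b in labels[i + 1:])
        if min_pair < config.min_interspecific:
            pad = (config.min_interspecific - min_pair) / 2.0
            stack = [sub.root]
            while stack:
                nd = stack.pop()
                if nd.is_leaf:
                    nd.edge_length += pad
                stack.extend(nd.children)
        sub.root.edge_length = config.between_genus_distance / 2.0
        root.children.append(sub.root)
    tree = PhyloTree(root)

    db, species_seqs, site_rates = sim_alignment(
        tree, config.model, config.n_sites, config.refs_per_species,
        config.intra_divergence, seed=int(rng.integers(2**31)),
        genus_map=genus_map, return_truth=True)

    # withhold species from the database (undescribed-species emulation);
    # only species with an in-database congener are eligible
    out_of_db = []
    n_out = int(round(config.frac_out_of_db * config.n_species))
    eligible = [sp for sp in species_names
                if sum(genus_map[s] == genus_map[sp] for s in species_names) > 1]
    for sp in eligible[:n_out]:
        out_of_db.append(sp)
    records = [r for r in db.records if r.species not in out_of_db]

    # mislabeled lineages: a reference at the victim's star center carrying
    # a congener's name — the closest possible record to every victim query
    mislabeled = []
    candidates = [sp for sp in species_names if sp not in out_of_db
                  and sum(genus_map[s] == genus_map[sp] for s in species_names
                          if s not in out_of_db) > 1]
    for v in range(config.n_mislabeled_lineages):
        victim = candidates[v]
        beneficiary = next(sp for sp in species_names
                           if sp != victim and sp not in out_of_db
                           and genus_map[sp] == genus_map[victim])
        records.append(TaxonRef(
            accession=f"MIS{v + 1:05d}", species=beneficiary,
            genus=genus_map[victim],
            aligned_seq=_decode(species_seqs[victim]),
            source_flags=frozenset({"suspected-mislabel"})))
        mislabeled.append((victim, beneficiary))
    refdb = ReferenceDB(records)

    # geometric skew over species for market sampling
    weights = config.query_skew ** np.arange(config.n_species)
    weights /= weights.sum()
    order = rng.permutation(config.n_species)
    sampled_species = [species_names[order[i]]
                       for i in rng.choice(config.n_species, size=config.n_queries,
                                           p=weights)]
    # guarantee every out-of-database and mislabeled lineage appears
    forced = out_of_db + [v for v, _ in mislabeled]
    for i, sp in enumerate(forced):
        if sp not in sampled_species and i < len(sampled_species):
            sampled_species[i] = sp

    queries = []
    label_map = {}
    for i, sp in enumerate(sampled_species):
        qseed = int(rng.integers(2**31))
        qrng = np.random.default_rng(qseed)
        qseq = _evolve(species_seqs[sp], config.intra_divergence / 2.0,
                       site_rates, config.model, qrng)
        sample_id = f"MKT{i + 1:04d}"
        template = _decode(qseq)
        if config.as_read_pairs:
            pair = sim_read_pair(template, seed=qseed, read_id=sample_id)
            queries.append((pair, sp))
        else:
            queries.append((ConsensusRecord(sample_id=sample_id,
                                            sequence=template), sp))
        label_map[sample_id] = "cação"

    cats = sorted(config.status_probs)
    probs = np.array([config.status_probs[c] for c in cats])
    rows = {}
    for sp in species_names:
        rows[sp] = {
            "global": cats[int(rng.choice(len(cats), p=probs))],
            "national": cats[int(rng.choice(len(cats), p=probs))],
            "regional_1": cats[int(rng.choice(len(cats), p=probs))],
            "regional_2": "absent",
        }
    status_table = ConservationStatusTable(rows)
    group_map = {sp: f"Order-{genus_map[sp]}" for sp in species_names}

    return SimScenario(
        config=config, true_tree=tree, model=config.model, refdb=refdb,
        queries=queries, label_map=label_map, status_table=status_table,
        group_map=group_map, mislabeled=mislabeled, out_of_db=out_of_db,
        seed=config.seed)
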