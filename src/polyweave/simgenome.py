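"""Synthetic allotetraploid evolution with full truth tracks.

The generator emulates the data configuration of a polyploid resequencing
study: two diploid progenitor proxies diverged from a common ancestor, a
panel of allotetraploid accessions whose A and D subgenomes evolve by
substitution along a fixed species tree, and error-bearing uniform-coverage
short reads. Planted events — homoeologous conversion tracts, duplications
and deletions, interspecies introgression blocks, and diploid autapomorphic
mutations — are recorded in an event ledger so downstream detectors can be
scored against truth.

The species tree is the seven-species allotetraploid topology with AD4 basal
to the split between the AD1 clade (AD1, AD6, AD7, with AD3 diverging first)
and the AD2 clade (AD2, AD5)::

    root ── AD4
         └─ core ── cladeA ── AD3
                 │         └─ n1 ── AD1
                 │               └─ n2 ── AD6
                 │                     └─ AD7
                 └─ cladeB ── AD2
                           └─ AD5

Each accession hangs from its species node by one further branch. Subgenomes
are haploid (highly inbred accessions genotyped as a per-subgenome
consensus) and the mutation model is substitution-only; structural change
enters solely through the explicit CNV events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _seq
from .reads import Reads

Genome = dict[str, np.ndarray]

# parent pointers of the fixed species tree
TREE_PARENT: dict[str, str | None] = {
    "root": None,
    "AD4": "root",
    "core": "root",
    "cladeA": "core",
    "cladeB": "core",
    "AD3": "cladeA",
    "n1": "cladeA",
    "AD1": "n1",
    "n2": "n1",
    "AD6": "n2",
    "AD7": "n2",
    "AD2": "cladeB",
    "AD5": "cladeB",
}

SPECIES = ("AD1", "AD2", "AD3", "AD4", "AD5", "AD6", "AD7")

# AD1/AD2-clade membership, used by tests and reports
CLADE_OF = {
    "AD1": "AD1", "AD3": "AD1", "AD6": "AD1", "AD7": "AD1",
    "AD2": "AD2", "AD5": "AD2",
    "AD4": "outgroup",
}


class SimulationError(ValueError):
    """Invalid simulator configuration or impossible event placement."""


@dataclass(frozen=True)
class ConversionSpec:
    """Homoeologous conversion tract planted on a species branch.

    ``target`` names the subgenome that is overwritten: target "D" means the
    A-subgenome allele replaces its D homoeolog (an A-dominant event).
    """

    species: str
    target: str  # "A" or "D"
    length: int
    count: int = 1


@dataclass(frozen=True)
class CNVSpec:
    """Duplication or deletion in one subgenome of one accession."""

    genome: str  # "A" or "D"
    kind: str  # "duplication" or "deletion"
    length: int
    count: int = 1
    accession: str | None = None  # default: first accession of AD1


@dataclass(frozen=True)
class IntrogressionSpec:
    """Donor-species block copied into a recipient ("cultivar") accession."""

    recipient: str
    donor_species: str
    length: int
    count: int = 1
    genome: str = "A"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic panel.

    Defaults mirror the study conditions at desk scale: ~1% progenitor
    divergence, 100 bp reads, ~20x coverage and 0.5% base error, a panel with
    multiple accessions for the two domesticated species and one accession
    for each wild species.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_chromosomes: int = 1
    branch_sub_prob: float = 0.002  # per site, per tree branch
    progenitor_divergence: float = 0.01  # total A-vs-D per-site divergence
    conversion_tracts: tuple[ConversionSpec, ...] = ()
    cnv_events: tuple[CNVSpec, ...] = ()
    introgression_blocks: tuple[IntrogressionSpec, ...] = ()
    autapomorphy_count: int = 0  # per diploid
    accessions: tuple[tuple[str, int], ...] = (
        ("AD1", 3), ("AD2", 3), ("AD3", 1), ("AD4", 1),
        ("AD5", 1), ("AD6", 1), ("AD7", 1),
    )
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise SimulationError("genome_length must be >= 1000")
        if self.n_chromosomes < 1:
            raise SimulationError("n_chromosomes must be >= 1")
        for p in (self.branch_sub_prob, self.progenitor_divergence,
                  self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.read_length <= 0:
            raise SimulationError("read_length must be > 0")
        for spec in self.conversion_tracts:
            if spec.species not in SPECIES or spec.species == "AD4":
                # AD4 is the outgroup; tracts are planted post-AD4-split
                if spec.species not in SPECIES:
                    raise SimulationError(f"unknown species {spec.species!r}")
            if spec.target not in ("A", "D") or spec.length <= 0:
                raise SimulationError(f"bad conversion spec {spec}")
        for spec in self.cnv_events:
            if spec.kind not in ("duplication", "deletion") or spec.length <= 0:
                raise SimulationError(f"bad CNV spec {spec}")
        for spec in self.introgression_blocks:
            if spec.donor_species not in SPECIES or spec.length <= 0:
                raise SimulationError(f"bad introgression spec {spec}")

    @property
    def accession_names(self) -> dict[str, list[str]]:
        return {
            sp: [f"{sp}_{i + 1}" for i in range(n)] for sp, n in self.accessions
        }

    def chrom_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lens = [base] * self.n_chromosomes
        lens[-1] += self.genome_length - base * self.n_chromosomes
        return {f"chr{i + 1}": L for i, L in enumerate(lens)}


@dataclass
class ProgenitorPair:
    """Ancestor plus the two diverged progenitor genomes."""

    ancestor: Genome
    genome_a: Genome
    genome_d: Genome
    divergence_sites: dict[str, np.ndarray]  # chrom -> positions

    def divergence_alleles(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        pos = self.divergence_sites[chrom]
        return self.genome_a[chrom][pos], self.genome_d[chrom][pos]

    def n_divergence_sites(self) -> int:
        return int(sum(p.size for p in self.divergence_sites.values()))


@dataclass
class Accession:
    name: str
    species: str
    genome_a: Genome
    genome_d: Genome

    def subgenome(self, which: str) -> Genome:
        return self.genome_a if which == "A" else self.genome_d


EVENT_COLUMNS = ["kind", "genome", "chrom", "start", "end", "branch"]


@dataclass
class PanelTruth:
    """Everything the simulator knows: sequences plus the event ledger."""

    config: SimConfig
    progenitors: ProgenitorPair
    diploid_a: Genome  # extant A-diploid proxy (progenitor + autapomorphies)
    diploid_d: Genome
    species_seqs: dict[str, tuple[Genome, Genome]]  # species node (A, D)
    accessions: dict[str, Accession]
    events: pd.DataFrame  # EVENT_COLUMNS

    def events_of(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind]

    def cnv_intervals(
        self, accession: str, subgenome: str, kind: str
    ) -> list[tuple[str, int, int]]:
        ev = self.events
        sel = ev[
            (ev["kind"] == kind)
            & (ev["genome"] == f"{accession}:{subgenome}")
        ]
        return list(zip(sel["chrom"], sel["start"], sel["end"]))


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_progenitors(config: SimConfig) -> ProgenitorPair:
    """Generate the ancestor and two independently diverged progenitors.

    Each progenitor branch receives independent per-site substitutions at
    half the total target divergence, so the expected A-vs-D difference rate
    is ~``progenitor_divergence`` (less a small coincident-hit correction).
    """
    rng = _rng(config, 0)
    p = config.progenitor_divergence / 2.0
    ancestor: Genome = {}
    genome_a: Genome = {}
    genome_d: Genome = {}
    sites: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths().items():
        anc = _seq.random_genome(rng, length)
        ga, _ = _seq.mutate_per_site(anc, p, rng)
        gd, _ = _seq.mutate_per_site(anc, p, rng)
        ancestor[chrom] = anc
        genome_a[chrom] = ga
        genome_d[chrom] = gd
        sites[chrom] = np.flatnonzero(ga != gd)
    return ProgenitorPair(ancestor, genome_a, genome_d, sites)


def _copy_genome(g: Genome) -> Genome:
    return {c: s.copy() for c, s in g.items()}


def _tree_paths() -> dict[str, list[str]]:
    """Root-to-species edge lists; edge named by its child node."""
    paths = {}
    for sp in SPECIES:
        path = []
        node = sp
        while TREE_PARENT[node] is not None:
            path.append(node)
            node = TREE_PARENT[node]
        paths[sp] = list(reversed(path))
    return paths


def _overlaps(start: int, end: int, intervals: list[tuple[str, int, int]],
              chrom: str) -> bool:
    return any(c == chrom and start < e and s < end for c, s, e in intervals)


def _place_interval(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    length: int,
    avoid: list[tuple[str, int, int]],
    max_tries: int = 200,
) -> tuple[str, int, int]:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        if chrom_lengths[chrom] <= length:
            continue
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        if not _overlaps(start, start + length, avoid, chrom):
            return chrom, start, start + length
    raise SimulationError(
        f"could not place an interval of length {length} without conflict"
    )


def simulate_polyploid_panel(
    progenitors: ProgenitorPair, config: SimConfig
) -> PanelTruth:
    """Evolve the accession panel on the species tree and plant all events.

    Order of operations per accession: branch substitutions down the tree,
    then introgression blocks (donor species-node consensus copied in), then
    conversion tracts (the target subgenome's tract is overwritten by the
    accession's own homoeologous alleles, so the two subgenomes are
    base-for-base identical across the tract in the output). CNV events do
    not alter sequence; they act at read-sampling time.
    """
    rng = _rng(config, 1)
    chrom_lengths = config.chrom_lengths()
    events: list[tuple] = []

    # --- diploid autapomorphies -------------------------------------------
    diploid_a = _copy_genome(progenitors.genome_a)
    diploid_d = _copy_genome(progenitors.genome_d)
    for label, genome in (("A2", diploid_a), ("D5", diploid_d)):
        for _ in range(config.autapomorphy_count):
            while True:
                chrom, start, end = _place_interval(
                    rng, chrom_lengths, 1, avoid=[]
                )
                div = progenitors.divergence_sites[chrom]
                if start not in div and genome[chrom][start] == \
                        progenitors.genome_a[chrom][start] == \
                        progenitors.genome_d[chrom][start]:
                    break
            _seq.mutate_at(genome[chrom], np.array([start]), rng)
            events.append(("autapomorphy", label, chrom, start, end, label))

    # --- evolve species-node sequences ------------------------------------
    node_seqs: dict[str, tuple[Genome, Genome]] = {
        "root": (progenitors.genome_a, progenitors.genome_d)
    }

    def evolve_edge(parent: str, child: str) -> None:
        pa, pd_ = node_seqs[parent]
        ga, gd = _copy_genome(pa), _copy_genome(pd_)
        for sub, g in (("A", ga), ("D", gd)):
            for chrom in g:
                g[chrom], hits = _seq.mutate_per_site(
                    g[chrom], config.branch_sub_prob, rng
                )
                for h in hits:
                    events.append(
                        ("mutation", sub, chrom, int(h), int(h) + 1, child)
                    )
        node_seqs[child] = (ga, gd)

    order = ["AD4", "core", "cladeA", "cladeB", "AD3", "n1", "AD1",
             "n2", "AD6", "AD7", "AD2", "AD5"]
    for child in order:
        evolve_edge(TREE_PARENT[child], child)

    # --- resolve conversion tract intervals per species --------------------
    conversion_iv: dict[str, list[tuple[str, int, int, str]]] = {}
    placed: list[tuple[str, int, int]] = []
    for spec in config.conversion_tracts:
        for _ in range(spec.count):
            chrom, start, end = _place_interval(
                rng, chrom_lengths, spec.length, avoid=placed
            )
            placed.append((chrom, start, end))
            conversion_iv.setdefault(spec.species, []).append(
                (chrom, start, end, spec.target)
            )

    # --- introgression block intervals per recipient -----------------------
    intro_iv: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for spec in config.introgression_blocks:
        for _ in range(spec.count):
            chrom, start, end = _place_interval(
                rng, chrom_lengths, spec.length, avoid=placed
            )
            placed.append((chrom, start, end))
            intro_iv.setdefault(spec.recipient, []).append(
                (chrom, start, end, spec.donor_species, spec.genome)
            )

    # --- accessions ---------------------------------------------------------
    accessions: dict[str, Accession] = {}
    for species, names in config.accession_names.items():
        for name in names:
            pa, pd_ = node_seqs[species]
            ga, gd = _copy_genome(pa), _copy_genome(pd_)
            for sub, g in (("A", ga), ("D", gd)):
                for chrom in g:
                    g[chrom], hits = _seq.mutate_per_site(
                        g[chrom], config.branch_sub_prob, rng
                    )
                    for h in hits:
                        events.append(
                            ("mutation", f"{name}:{sub}", chrom,
                             int(h), int(h) + 1, name)
                        )
            # introgression: donor species-node consensus replaces the block
            for chrom, start, end, donor, sub in intro_iv.get(name, []):
                donor_g = node_seqs[donor][0 if sub == "A" else 1]
                target = ga if sub == "A" else gd
                target[chrom][start:end] = donor_g[chrom][start:end]
                events.append(
                    ("introgression", f"{name}:{sub}", chrom, start, end,
                     donor)
                )
            # conversion: overwrite target subgenome with its homoeolog
            for chrom, start, end, target_sub in conversion_iv.get(
                species, []
            ):
                src, dst = (gd, ga) if target_sub == "A" else (ga, gd)
                dst[chrom][start:end] = src[chrom][start:end]
                events.append(
                    ("conversion", f"{name}:{target_sub}", chrom, start, end,
                     species)
                )
            accessions[name] = Accession(name, species, ga, gd)

    # --- CNV events ---------------------------------------------------------
    deletion_iv: list[tuple[str, int, int]] = []
    for spec in config.cnv_events:
        target_acc = spec.accession
        if target_acc is None:
            target_acc = next(iter(accessions))
        if target_acc not in accessions:
            raise SimulationError(f"unknown accession {target_acc!r}")
        for _ in range(spec.count):
            chrom, start, end = _place_interval(
                rng, chrom_lengths, spec.length, avoid=placed
            )
            placed.append((chrom, start, end))
            if spec.kind == "deletion":
                deletion_iv.append((chrom, start, end))
            events.append(
                (spec.kind, f"{target_acc}:{spec.genome}", chrom, start, end,
                 target_acc)
            )

    # conversion tracts must not fall inside deletions (no reads -> no signal)
    for iv_list in conversion_iv.values():
        for chrom, start, end, _t in iv_list:
            if _overlaps(start, end, deletion_iv, chrom):
                raise SimulationError(
                    "conversion tract overlaps a planted deletion"
                )

    species_seqs = {sp: node_seqs[sp] for sp in SPECIES}
    ledger = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return PanelTruth(
        config=config,
        progenitors=progenitors,
        diploid_a=diploid_a,
        diploid_d=diploid_d,
        species_seqs=species_seqs,
        accessions=accessions,
        events=ledger,
    )


def simulate_reads(
    genomes: dict[str, Genome],
    depth: float,
    read_length: int,
    error_rate: float,
    seed,
    deletions: dict[str, list[tuple[str, int, int]]] | None = None,
    duplications: dict[str, list[tuple[str, int, int]]] | None = None,
    name_prefix: str = "read",
) -> tuple[Reads, pd.DataFrame]:
    """Draw uniform reads from one or more (sub)genome copies.

    ``genomes`` maps a source label (e.g. subgenome "A"/"D") to its
    chromosome sequences. Per chromosome copy, ``round(depth * L /
    read_length)`` start positions are drawn uniformly; reads overlapping a
    deleted interval of that source are discarded, and duplicated intervals
    contribute a second round of reads at the same rate, doubling local
    coverage. Substitution errors hit each base independently at
    ``error_rate``. Returns the reads and an origin ledger with the true
    source, chromosome and start of every read.
    """
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    rng = np.random.default_rng(seed)
    deletions = deletions or {}
    duplications = duplications or {}
    all_codes: list[np.ndarray] = []
    names: list[str] = []
    origin: list[tuple] = []
    counter = 0
    for source, genome in genomes.items():
        for chrom, codes in genome.items():
            L = codes.shape[0]
            if read_length > L:
                raise SimulationError(
                    f"read_length {read_length} exceeds {chrom} length {L}"
                )
            n = int(round(depth * L / read_length))
            starts = rng.integers(0, L - read_length + 1, size=n)
            dels = [
                (s, e) for c, s, e in deletions.get(source, []) if c == chrom
            ]
            if dels:
                keep = np.ones(n, dtype=bool)
                for s, e in dels:
                    keep &= ~(
                        (starts < e) & (starts + read_length > s)
                    )
                starts = starts[keep]
            extra = []
            for c, s, e in duplications.get(source, []):
                if c != chrom or e - s < read_length:
                    continue
                n_dup = int(round(depth * (e - s) / read_length))
                extra.append(
                    rng.integers(s, e - read_length + 1, size=n_dup)
                )
            if extra:
                starts = np.concatenate([starts] + extra)
            if starts.size == 0:
                continue
            # gather read matrices via fancy indexing
            idx = starts[:, None] + np.arange(read_length)[None, :]
            mat = codes[idx]
            for s in starts:
                names.append(f"{name_prefix}_{counter}")
                origin.append((f"{name_prefix}_{counter}", source, chrom,
                               int(s)))
                counter += 1
            all_codes.append(mat)
    if not all_codes:
        raise SimulationError("no reads generated")
    codes = np.concatenate(all_codes, axis=0)
    if error_rate > 0:
        hits = rng.random(codes.shape) < error_rate
        shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
        codes = np.where(hits, (codes + shift) % 4, codes).astype(np.uint8)
    ledger = pd.DataFrame(origin, columns=["read", "source", "chrom", "start"])
    reads = Reads(names, codes)
    return reads, ledger


def truth_genotype_matrix(
    truth: PanelTruth, sites: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-subgenome base calls read directly off the simulated assemblies.

    Rows are (chrom, pos); columns are a MultiIndex (accession, subgenome)
    plus the diploid proxies under accession "A2"/"D5" (subgenome "A"/"D"
    respectively). This is the noise-free genotype matrix used to exercise
    detection logic independently of read-level error.
    """
    cols: dict[tuple[str, str], list[str]] = {}
    index: list[tuple[str, int]] = [
        (chrom, int(p)) for chrom, pos in sites.items() for p in pos
    ]

    def col_for(genome: Genome) -> list[str]:
        out = []
        for chrom, pos in sites.items():
            out.extend(_seq.BASES[b] for b in genome[chrom][pos])
        return out

    cols[("A2", "A")] = col_for(truth.diploid_a)
    cols[("D5", "D")] = col_for(truth.diploid_d)
    for name, acc in truth.accessions.items():
        cols[(name, "A")] = col_for(acc.genome_a)
        cols[(name, "D")] = col_for(acc.genome_d)
    df = pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(
        index, names=["chrom", "pos"]))
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["accession", "subgenome"])
    return df
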