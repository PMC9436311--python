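"""Base-pair-resolution, gene-panel-restricted mutation model.

Every simulated keratinocyte carries an in silico genome restricted to a
panel of genes (72 by default, mirroring targeted deep-sequencing panels
used for normal skin).  Each gene ``g`` has a length ``L_g`` (bp), a base
composition, and a gene-specific mutation rate ``mu_g`` in mutations per
base pair per division, normalized so that the length-weighted mean rate
hits a configurable target (default 3.2e-9 bp^-1 division^-1).  At every
division the number of de novo substitutions in gene ``g`` is drawn as
``X_g ~ Poisson(mu_g * L_g)``; the reference base of each substitution is
drawn from a base-class multinomial that puts probability 0.5 on cytosine
(the UV signature of skin: an excess of C>T transitions) and 1/6 on each of
A, G, T, renormalized over the base classes actually present in the gene;
the position is uniform among positions holding that base.  All ancestral
mutations are inherited by daughter cells, so individual base changes act
as intrinsic cell-fate markers readable by (virtual) sequencing.

Coordinates are 0-based, half-open ``[start, end)`` (BED convention), so
``L_g = end - start``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "DRIVER_CLASSES",
    "DEFAULT_TARGET_MEAN_RATE",
    "PanelParseError",
    "MutationEvent",
    "Genotype",
    "GenePanel",
    "build_gene_panel",
    "normalize_rates",
    "draw_mutation_count",
    "draw_mutation",
    "sample_events",
    "inherit_and_mutate",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_mutation_table",
    "write_vcf",
]

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DRIVER_CLASSES = ("passenger", "NOTCH1-like", "TP53-like")

#: mean somatic mutation rate per bp per division the default panel is
#: normalized to (a conservative estimate for normal epidermis).
DEFAULT_TARGET_MEAN_RATE = 3.2e-9

#: base-class weights of the UV mutational signature: half of all events
#: originate at a cytosine, the remainder split evenly.
DEFAULT_BASE_WEIGHTS = {"A": 1.0 / 6.0, "C": 0.5, "G": 1.0 / 6.0, "T": 1.0 / 6.0}

#: substitution model: for a cytosine reference the alternate is T with
#: probability 0.9 (C>T transitions dominate), otherwise uniform over the
#: remaining bases; for non-C references the alternate is uniform.
DEFAULT_C_TO_T_PROB = 0.9

_PANEL_COLUMNS = ["gene", "chrom", "start", "end", "nA", "nC", "nG", "nT", "mu_g", "driver_class"]


class PanelParseError(ValueError):
    """Raised for malformed gene-panel tables; carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class MutationEvent:
    """A single somatic substitution, usable as a heritable cell-fate marker."""

    id: int
    gene: str
    position: int
    ref_base: str
    alt_base: str
    birth_time: float
    parent_lineage: int = -1

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")


class Genotype:
    """A node in the persistent lineage tree of mutation sets.

    A genotype stores only its own de novo events plus a reference to the
    genotype it arose in; the full mutation set is the union along the
    ancestor chain, so sibling genotypes share ancestral structure.
    """

    __slots__ = ("id", "parent", "own_events", "has_notch1", "has_tp53")

    def __init__(self, id: int, parent: "Genotype | None", own_events: Sequence[MutationEvent],
                 driver_class_of: dict[str, str] | None = None):
        self.id = id
        self.parent = parent
        self.own_events = tuple(own_events)
        has_n1 = parent.has_notch1 if parent is not None else False
        has_p53 = parent.has_tp53 if parent is not None else False
        if driver_class_of:
            for ev in self.own_events:
                cls = driver_class_of.get(ev.gene, "passenger")
                if cls == "NOTCH1-like":
                    has_n1 = True
                elif cls == "TP53-like":
                    has_p53 = True
        self.has_notch1 = has_n1
        self.has_tp53 = has_p53

    def iter_events(self) -> Iterator[MutationEvent]:
        """All mutations carried by this genotype, oldest lineage first."""
        chain = []
        node: Genotype | None = self
        while node is not None:
            chain.append(node)
            node = node.parent
        for node in reversed(chain):
            yield from node.own_events

    def mutation_ids(self) -> tuple[int, ...]:
        return tuple(ev.id for ev in self.iter_events())

    def __contains__(self, mutation_id: int) -> bool:
        return any(ev.id == mutation_id for ev in self.iter_events())

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_events())


class GenePanel:
    """A gene panel: per-gene coordinates, base composition and mutation rate.

    Positions of individual bases within a gene are realized lazily from the
    stored base counts as a deterministic (seeded) arrangement, so repeated
    draws at the same position always see the same reference base.  Panels
    loaded from real tables carry composition counts only; the synthetic
    arrangement stands in for the actual sequence.
    """

    def __init__(self, table: pd.DataFrame, arrangement_seed: int = 0,
                 base_weights: dict[str, float] | None = None,
                 c_to_t_prob: float = DEFAULT_C_TO_T_PROB):
        table = table.reset_index(drop=True)
        missing = [c for c in _PANEL_COLUMNS if c not in table.columns]
        if missing:
            raise PanelParseError(f"panel table missing columns: {missing}")
        self.table = table.loc[:, _PANEL_COLUMNS].copy()
        self.arrangement_seed = int(arrangement_seed)
        self.base_weights = dict(base_weights or DEFAULT_BASE_WEIGHTS)
        self.c_to_t_prob = float(c_to_t_prob)
        self._validate()
        self._positions_cache: dict[int, list[np.ndarray]] = {}
        self._ref_weight_cum: np.ndarray | None = None

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        t = self.table
        for i, row in t.iterrows():
            L = int(row.end) - int(row.start)
            if L <= 0:
                raise PanelParseError(f"gene {row.gene!r}: end <= start")
            counts = int(row.nA) + int(row.nC) + int(row.nG) + int(row.nT)
            if counts != L:
                raise PanelParseError(
                    f"gene {row.gene!r}: base counts sum to {counts}, length is {L}")
            if not row.mu_g > 0:
                raise PanelParseError(f"gene {row.gene!r}: mu_g must be > 0")
            if row.driver_class not in DRIVER_CLASSES:
                raise PanelParseError(f"gene {row.gene!r}: unknown driver_class {row.driver_class!r}")
        if t.gene.duplicated().any():
            raise PanelParseError("duplicate gene names in panel")

    # -- basic accessors ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.gene)

    @property
    def lengths(self) -> np.ndarray:
        return (self.table.end - self.table.start).to_numpy(dtype=np.int64)

    @property
    def rates(self) -> np.ndarray:
        return self.table.mu_g.to_numpy(dtype=float)

    @property
    def expected_mutations_per_division(self) -> np.ndarray:
        """Per-gene Poisson means mu_g * L_g."""
        return self.rates * self.lengths

    @property
    def total_rate_per_division(self) -> float:
        """Expected de novo substitutions per division over the whole panel."""
        return float(self.expected_mutations_per_division.sum())

    def weighted_mean_rate(self) -> float:
        """Length-weighted mean rate sum(mu_g * L_g) / sum(L_g)."""
        L = self.lengths
        return float((self.rates * L).sum() / L.sum())

    def gene_index(self, gene: str) -> int:
        idx = self.table.index[self.table.gene == gene]
        if len(idx) == 0:
            raise KeyError(gene)
        return int(idx[0])

    def driver_class_of(self) -> dict[str, str]:
        return dict(zip(self.table.gene, self.table.driver_class))

    def base_counts(self, gene_idx: int) -> np.ndarray:
        row = self.table.iloc[gene_idx]
        return np.array([row.nA, row.nC, row.nG, row.nT], dtype=np.int64)

    # -- sequence arrangement -------------------------------------------------

    def positions_of(self, gene_idx: int) -> list[np.ndarray]:
        """Genomic positions of each base class within a gene.

        The arrangement is a seeded shuffle consistent with the stored base
        counts; it is fixed for the lifetime of the panel (and across panels
        built with the same seed), so a position always maps to one base.
        """
        cached = self._positions_cache.get(gene_idx)
        if cached is not None:
            return cached
        row = self.table.iloc[gene_idx]
        counts = self.base_counts(gene_idx)
        codes = np.repeat(np.arange(4, dtype=np.int8), counts)
        rng = np.random.default_rng((self.arrangement_seed, 7919, gene_idx))
        rng.shuffle(codes)
        start = int(row.start)
        positions = [start + np.nonzero(codes == b)[0] for b in range(4)]
        self._positions_cache[gene_idx] = positions
        return positions

    # -- per-gene base-class weights ------------------------------------------

    def ref_base_cumweights(self) -> np.ndarray:
        """(G, 4) cumulative base-class weights, renormalized per gene over
        the base classes present (a gene missing e.g. all G redistributes
        that mass over its remaining classes)."""
        if self._ref_weight_cum is None:
            counts = self.table[["nA", "nC", "nG", "nT"]].to_numpy(dtype=float)
            w = np.array([self.base_weights[b] for b in BASES], dtype=float)
            weights = np.where(counts > 0, w, 0.0)
            totals = weights.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError("gene with no positively weighted base class")
            self._ref_weight_cum = np.cumsum(weights / totals, axis=1)
        return self._ref_weight_cum

    def with_table(self, table: pd.DataFrame) -> "GenePanel":
        return GenePanel(table, arrangement_seed=self.arrangement_seed,
                         base_weights=self.base_weights, c_to_t_prob=self.c_to_t_prob)


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_gene_panel(n_genes: int = 72,
                     length_range: tuple[float, float] = (2_000.0, 120_000.0),
                     gc_fraction: float = 0.41,
                     target_mean_rate: float = DEFAULT_TARGET_MEAN_RATE,
                     rate_dispersion: float = 0.5,
                     seed: int = 0,
                     table: pd.DataFrame | str | None = None) -> GenePanel:
    """Build a gene panel, synthetic by default or from a TSV table.

    The synthetic default emulates a 72-gene targeted panel: gene lengths
    log-uniform on ``length_range``, GC fraction ``gc_fraction``, per-gene
    rates log-normally dispersed (``rate_dispersion`` is the sigma of
    log mu_g) then normalized so the length-weighted mean rate equals
    ``target_mean_rate``.  Exactly one gene is labeled NOTCH1-like and one
    TP53-like (with lengths typical of those loci); all others are
    passengers.  ``table`` (DataFrame or TSV path) overrides synthesis.
    """
    if table is not None:
        if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
            return read_panel_tsv(table)
        return GenePanel(table, arrangement_seed=seed)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 100:
        raise ValueError("gene lengths must be >= 100 bp")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes)).astype(np.int64)
    names = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    chroms = [f"chr{rng.integers(1, 23)}" for _ in range(n_genes)]
    driver = ["passenger"] * n_genes
    if n_genes >= 2:
        names[0], chroms[0], driver[0], lengths[0] = "NOTCH1", "chr9", "NOTCH1-like", 51_000
        names[1], chroms[1], driver[1], lengths[1] = "TP53", "chr17", "TP53-like", 19_000
    elif n_genes == 1:
        pass  # a single-gene panel stays a passenger panel
    starts = np.zeros(n_genes, dtype=np.int64)
    offset = 1_000_000
    for i in range(n_genes):
        starts[i] = offset
        offset += lengths[i] + 10_000
    pC = gc_fraction / 2.0
    pA = (1.0 - gc_fraction) / 2.0
    counts = np.vstack([rng.multinomial(L, [pA, pC, pC, pA]) for L in lengths])
    mu = np.exp(rng.normal(0.0, rate_dispersion, size=n_genes))
    tbl = pd.DataFrame({
        "gene": names, "chrom": chroms,
        "start": starts, "end": starts + lengths,
        "nA": counts[:, 0], "nC": counts[:, 1], "nG": counts[:, 2], "nT": counts[:, 3],
        "mu_g": mu, "driver_class": driver,
    })
    panel = GenePanel(tbl, arrangement_seed=seed)
    return normalize_rates(panel, target_mean_rate)


def normalize_rates(panel: GenePanel, target_mean: float) -> GenePanel:
    """Scale all per-gene rates by one global factor so the length-weighted
    mean sum(mu_g * L_g) / sum(L_g) equals ``target_mean``."""
    if not target_mean > 0:
        raise ValueError("target_mean must be > 0")
    current = panel.weighted_mean_rate()
    tbl = panel.table.copy()
    tbl["mu_g"] = tbl["mu_g"] * (target_mean / current)
    return panel.with_table(tbl)


# ---------------------------------------------------------------------------
# mutation draws
# ---------------------------------------------------------------------------

def draw_mutation_count(panel: GenePanel, gene_idx: int, rng: np.random.Generator) -> int:
    """Number of de novo substitutions in one gene at one division,
    X_g ~ Poisson(mu_g * L_g)."""
    lam = panel.expected_mutations_per_division[gene_idx]
    return int(rng.poisson(lam))


def _draw_ref_base(panel: GenePanel, gene_idx: int, rng: np.random.Generator) -> int:
    cum = panel.ref_base_cumweights()[gene_idx]
    return int(np.searchsorted(cum, rng.random(), side="right"))


def _draw_alt_base(panel: GenePanel, ref_code: int, rng: np.random.Generator) -> int:
    others = [b for b in range(4) if b != ref_code]
    if ref_code == _BASE_INDEX["C"]:
        if rng.random() < panel.c_to_t_prob:
            return _BASE_INDEX["T"]
        rest = [b for b in others if b != _BASE_INDEX["T"]]
        return rest[rng.integers(len(rest))]
    return others[rng.integers(3)]


def draw_mutation(panel: GenePanel, gene_idx: int, time: float, rng: np.random.Generator,
                  mut_id: int = 0, parent_lineage: int = -1,
                  exclude_positions: set[int] | None = None) -> MutationEvent:
    """Draw a single substitution in a gene.

    Reference base per the UV base-class multinomial (renormalized over base
    classes present in the gene); position uniform among positions holding
    that base; alternate base per the substitution model.  A position in
    ``exclude_positions`` (already mutated within the lineage) is redrawn:
    infinite sites within a lineage.
    """
    gene = panel.table.iloc[gene_idx]
    for _ in range(1000):
        ref_code = _draw_ref_base(panel, gene_idx, rng)
        pos_arr = panel.positions_of(gene_idx)[ref_code]
        pos = int(pos_arr[rng.integers(len(pos_arr))])
        if exclude_positions and pos in exclude_positions:
            continue
        alt_code = _draw_alt_base(panel, ref_code, rng)
        return MutationEvent(id=mut_id, gene=str(gene.gene), position=pos,
                             ref_base=BASES[ref_code], alt_base=BASES[alt_code],
                             birth_time=float(time), parent_lineage=parent_lineage)
    raise RuntimeError("could not draw an unused position (lineage saturates gene)")


def sample_events(panel: GenePanel, n: int, rng: np.random.Generator,
                  time: float = 0.0) -> pd.DataFrame:
    """Vectorized draw of ``n`` independent substitutions from the panel.

    Genes are chosen proportionally to their Poisson means mu_g * L_g (the
    stationary gene mix of the division-by-division process); base, position
    and alternate follow the same per-event model as :func:`draw_mutation`.
    Returns columns gene, chrom, pos, ref, alt, birth_time.
    """
    lam = panel.expected_mutations_per_division
    p = lam / lam.sum()
    gidx = rng.choice(len(panel), size=n, p=p)
    cum = panel.ref_base_cumweights()
    u = rng.random(n)
    ref = (u[:, None] > cum[gidx]).sum(axis=1).astype(np.int8)
    pos = np.empty(n, dtype=np.int64)
    alt = np.empty(n, dtype=np.int8)
    u_pos = rng.random(n)
    u_alt = rng.random(n)
    u_alt2 = rng.random(n)
    c_code = _BASE_INDEX["C"]
    t_code = _BASE_INDEX["T"]
    for g in np.unique(gidx):
        positions = panel.positions_of(int(g))
        sel_g = gidx == g
        for code in range(4):
            sel = sel_g & (ref == code)
            if not sel.any():
                continue
            arr = positions[code]
            pos[sel] = arr[(u_pos[sel] * len(arr)).astype(np.int64)]
    # alternate base
    for code in range(4):
        sel = ref == code
        if not sel.any():
            continue
        others = np.array([b for b in range(4) if b != code])
        if code == c_code:
            take_t = u_alt[sel] < panel.c_to_t_prob
            rest = np.array([b for b in others if b != t_code])
            alt_sel = np.where(take_t, t_code, rest[(u_alt2[sel] * 2).astype(np.int64)])
        else:
            alt_sel = others[(u_alt[sel] * 3).astype(np.int64)]
        alt[sel] = alt_sel
    base_arr = np.array(BASES)
    tbl = panel.table
    return pd.DataFrame({
        "gene": tbl.gene.to_numpy()[gidx],
        "chrom": tbl.chrom.to_numpy()[gidx],
        "pos": pos,
        "ref": base_arr[ref],
        "alt": base_arr[alt],
        "birth_time": time,
    })


def inherit_and_mutate(parent: Genotype | None, panel: GenePanel, time: float,
                       rng: np.random.Generator, next_mut_id: int = 0,
                       forced_counts: Sequence[int] | None = None,
                       next_genotype_id: int = 0) -> Genotype:
    """Produce a daughter genotype: all ancestral mutations plus per-gene
    Poisson de novo events.

    ``forced_counts`` overrides the Poisson draw (testing hook).  New
    mutation ids start at ``next_mut_id`` and increase in birth order.
    """
    if forced_counts is None:
        counts = rng.poisson(panel.expected_mutations_per_division)
    else:
        counts = np.asarray(forced_counts, dtype=np.int64)
    events: list[MutationEvent] = []
    if counts.sum() > 0:
        parent_id = parent.id if parent is not None else -1
        lineage_positions: set[int] | None = None
        for g in np.nonzero(counts)[0]:
            for _ in range(int(counts[g])):
                if lineage_positions is None:
                    lineage_positions = set()
                    node = parent
                    while node is not None:
                        lineage_positions.update(ev.position for ev in node.own_events)
                        node = node.parent
                lineage_positions.update(ev.position for ev in events)
                ev = draw_mutation(panel, int(g), time, rng, mut_id=next_mut_id,
                                   parent_lineage=parent_id,
                                   exclude_positions=lineage_positions)
                events.append(ev)
                next_mut_id += 1
    if not events and parent is not None:
        # no de novo events: daughter shares the parent genotype node
        return parent
    return Genotype(next_genotype_id, parent, events, panel.driver_class_of())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: GenePanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, arrangement_seed: int = 0) -> GenePanel:
    """Read a gene-panel TSV (header row required, tab-separated).

    Malformed rows raise :class:`PanelParseError` naming the 1-based line
    number (header is line 1).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PanelParseError("empty panel file")
    header = lines[0].split("\t")
    if header != _PANEL_COLUMNS:
        raise PanelParseError(f"line 1: expected header {_PANEL_COLUMNS}, got {header}")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_PANEL_COLUMNS):
            raise PanelParseError(f"line {i}: expected {len(_PANEL_COLUMNS)} columns, got {len(fields)}")
        try:
            rec = {
                "gene": fields[0], "chrom": fields[1],
                "start": int(fields[2]), "end": int(fields[3]),
                "nA": int(fields[4]), "nC": int(fields[5]),
                "nG": int(fields[6]), "nT": int(fields[7]),
                "mu_g": float(fields[8]), "driver_class": fields[9],
            }
        except ValueError as exc:
            raise PanelParseError(f"line {i}: {exc}") from exc
        if rec["end"] <= rec["start"]:
            raise PanelParseError(f"line {i}: end <= start")
        records.append(rec)
    try:
        return GenePanel(pd.DataFrame(records), arrangement_seed=arrangement_seed)
    except PanelParseError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PanelParseError(str(exc)) from exc


def write_mutation_table(mutations: Iterable[MutationEvent], n_cells: dict[int, int],
                         panel: GenePanel, path) -> pd.DataFrame:
    """Export mutations as TSV: id, gene, chrom, pos, ref, alt, birth_day, n_cells."""
    chrom_of = dict(zip(panel.table.gene, panel.table.chrom))
    rows = [{
        "id": ev.id, "gene": ev.gene, "chrom": chrom_of.get(ev.gene, "."),
        "pos": ev.position, "ref": ev.ref_base, "alt": ev.alt_base,
        "birth_day": ev.birth_time, "n_cells": n_cells.get(ev.id, 0),
    } for ev in mutations]
    df = pd.DataFrame(rows, columns=["id", "gene", "chrom", "pos", "ref", "alt",
                                     "birth_day", "n_cells"])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_vcf(mutations: Iterable[MutationEvent], n_cells: dict[int, int],
              panel: GenePanel, path) -> None:
    """Minimal VCF export of the mutation registry (sites only, no samples).

    INFO carries NC (cells carrying the variant at simulation end) and BD
    (birth day).  Coordinates are converted to 1-based per VCF.
    """
    chrom_of = dict(zip(panel.table.gene, panel.table.chrom))
    contigs = sorted(set(panel.table.chrom), key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epidermis-evo\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=NC,Number=1,Type=Integer,Description="Number of cells carrying the variant">\n')
        fh.write('##INFO=<ID=BD,Number=1,Type=Float,Description="Birth day of the mutation">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = sorted(mutations, key=lambda ev: (chrom_of.get(ev.gene, "."), ev.position))
        for ev in rows:
            fh.write(f"{chrom_of.get(ev.gene, '.')}\t{ev.position + 1}\t{ev.id}\t"
                     f"{ev.ref_base}\t{ev.alt_base}\t.\tPASS\t"
                     f"NC={n_cells.get(ev.id, 0)};BD={ev.birth_time:g}\n")
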