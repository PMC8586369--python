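"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes, not
transcriptome biology:

* clone sizes are log-normal, with multiplicative tissue-bias factors for
  planted tissue-tropic clones;
* barcode amplicon reads are a multinomial draw over clone proportions at a
  configurable depth (or an exact largest-remainder apportionment in
  noise-free mode), each read being flank5 + barcode + flank3 with an
  optional per-base substitution error;
* UMI counts are negative binomial (variance = mu + mu^2/dispersion) with a
  log-normal per-cell library size and planted fold changes on designated
  genes in one clone group; a planted subset of cells gets a mitochondrial
  UMI fraction strictly above the 10% filter threshold, all other cells
  strictly below it, so filter truth is exact;
* bridge reads cover a configurable fraction of cells (default 0.2, the
  mapped fraction observed in real data) and a configurable fraction of
  covered cells additionally emit a read carrying a wrong clone barcode,
  forcing multimap exclusion.

All randomness flows from the single ``seed`` in :class:`SimulationConfig`;
re-runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .barcode_quant import BarcodeLibrarySpec, SampleMeta
from . import io as ctio

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "random_barcodes",
    "simulate_barcode_reads",
    "simulate_sc_counts",
    "simulate_bridge_reads",
    "simulate_serial_transplant",
    "simulate_abundance_cohort",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))

DEFAULT_FLANK5 = "TCGATTAGCGCA"
DEFAULT_FLANK3 = "GCTAATGCGTCA"
DEFAULT_BARCODE_LENGTH = 20
CELL_INDEX_LENGTH = 16


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults follow the experimental design the pipeline targets: ~50 clones
    per cohort with log-normal(0, 1) sizes, 1e5 amplicon reads per sorted
    sample, a handful of strongly (10x) tissue-tropic clones, 10x-channel
    scale of ~1000 cells x 500 genes with NB dispersion 2, ~20% bridge
    coverage and a small multimap contamination rate.
    """

    n_clones: int = 50
    clone_lognormal_mu: float = 0.0
    clone_lognormal_sigma: float = 1.0
    tissues: tuple[str, ...] = ("blood", "spleen", "ovary")
    biased_tissue: str = "ovary"
    n_biased_clones: int = 5
    bias_multiplier: float = 10.0
    n_mice: int = 3
    mouse_jitter_sigma: float = 0.3
    tissue_noise_sigma: float = 0.25
    read_depth: int = 100_000
    barcode_error_rate: float = 0.0
    frac_human_of_mnc: float = 0.6
    frac_gfp_of_human: float = 0.5
    # single-cell channel
    n_cells: int = 1000
    n_genes: int = 500
    n_mito_genes: int = 10
    nb_dispersion: float = 2.0
    gene_mean_log_mu: float = np.log(2.0)
    gene_mean_log_sigma: float = 1.0
    libsize_sigma: float = 0.3
    planted_de: tuple[tuple[int, str, float], ...] = ()  # (gene index, "a"|"b", fold)
    group_a_clones: tuple[int, ...] | None = None  # clone indices; default first half
    mito_beta_a: float = 2.0
    mito_beta_b: float = 48.0
    frac_high_mito: float = 0.05
    # bridges
    bridge_coverage: float = 0.2
    bridge_multimap_rate: float = 0.02
    # modes
    exact_counts: bool = False      # noise-free read apportionment
    expression_noise: bool = True   # False freezes UMI counts at expected values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ValueError("n_clones must be >= 2")
        for name in ("frac_human_of_mnc", "frac_gfp_of_human", "bridge_coverage",
                     "bridge_multimap_rate", "frac_high_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_expr_genes = self.n_genes - self.n_mito_genes
        for gene_idx, group, fold in self.planted_de:
            if not 0 <= gene_idx < n_expr_genes:
                raise ValueError(f"planted DE gene index {gene_idx} out of range "
                                 f"[0, {n_expr_genes})")
            if group not in ("a", "b"):
                raise ValueError("planted DE group must be 'a' or 'b'")
            if fold <= 0:
                raise ValueError("planted DE fold change must be > 0")
        if self.n_biased_clones > self.n_clones:
            raise ValueError("more biased clones than clones")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    clone_barcodes: list[str]
    proportions: dict[str, dict[str, float]]  # sample -> barcode -> true proportion
    read_counts: dict[str, dict[str, int]]    # sample -> barcode -> emitted reads
    cell_clone: dict[str, str]                # cell index -> barcode
    covered_cells: list[str]
    multimapped_cells: list[str]
    high_mito_cells: list[str]
    de_genes_up_in_a: list[str]
    de_genes_up_in_b: list[str]
    group_a_barcodes: list[str]
    group_b_barcodes: list[str]
    biased_clones: list[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    library: BarcodeLibrarySpec
    reads_per_sample: dict[str, list[tuple[str, str]]]
    metas: dict[str, SampleMeta]
    adata: ad.AnnData
    bridge_reads: list[tuple[str, str]]
    truth: GroundTruth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sample in sorted(self.reads_per_sample):
            ctio.write_fastq(out / f"{sample}.fastq", self.reads_per_sample[sample])
        ctio.write_meta_csv(out / "meta.csv", [self.metas[s] for s in sorted(self.metas)])
        ctio.write_mtx_channel(self.adata, out / "channel1")
        ctio.write_fasta(out / "bridges.fasta", self.bridge_reads)
        (out / "clones.txt").write_text(
            "\n".join(self.truth.clone_barcodes) + "\n")
        (out / "library.json").write_text(json.dumps({
            "upstream_flank": self.library.upstream_flank,
            "downstream_flank": self.library.downstream_flank,
            "barcode_length": self.library.barcode_length,
        }, indent=2))
        self.truth.to_json(out / "truth.json")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random ACGT strings of the given length."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = _random_seq(rng, length)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` matching proportions exactly in
    expectation and deterministically (noise-free mode)."""
    raw = proportions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_barcode_reads(
    proportions: dict[str, float],
    depth: int,
    library: BarcodeLibrarySpec,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    exact: bool = False,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Amplicon reads for one sorted sample.

    Returns (reads, true per-clone read counts).  Reads are multinomial over
    the clone proportions (or a largest-remainder exact apportionment when
    ``exact``); each read is flank5 + barcode + flank3 with optional per-base
    substitution errors.
    """
    if depth <= 0:
        raise ValueError("read depth must be > 0")
    barcodes = sorted(proportions)
    p = np.array([proportions[b] for b in barcodes], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if exact:
        counts = _largest_remainder(p, depth)
    else:
        counts = rng.multinomial(depth, p)
    reads: list[tuple[str, str]] = []
    i = 0
    for bc, c in zip(barcodes, counts):
        for _ in range(int(c)):
            seq = library.upstream_flank + bc + library.downstream_flank
            if error_rate > 0:
                seq = _mutate(seq, error_rate, rng)
            reads.append((f"read{i:07d}", seq))
            i += 1
    return reads, {b: int(c) for b, c in zip(barcodes, counts)}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        for i in np.flatnonzero(hit):
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return "".join(arr)


def simulate_sc_counts(
    config: SimulationConfig,
    cell_clone: dict[str, str],
    group_a_barcodes: set[str],
    rng: np.random.Generator,
) -> tuple[ad.AnnData, list[str]]:
    """Negative-binomial UMI counts with planted fold changes and mito fractions.

    Returns the raw-count AnnData (cells x genes) and the list of planted
    high-mito cells.  Mitochondrial totals are derived from a drawn target
    fraction — clipped strictly below the 10% threshold for normal cells and
    strictly above it for planted high-mito cells — so filter ground truth is
    exact by construction.

    With ``config.expression_noise`` off, counts are the rounded expected
    values (unit library sizes, even mito allocation): the noise-free regime
    where the whole pipeline must reproduce truth exactly.
    """
    cells = sorted(cell_clone)
    n_cells = len(cells)
    n_mito = config.n_mito_genes
    n_expr = config.n_genes - n_mito
    genes = [f"MT-{i + 1}" for i in range(n_mito)] + \
            [f"GENE{i + 1:04d}" for i in range(n_expr)]

    mu_g = rng.lognormal(config.gene_mean_log_mu, config.gene_mean_log_sigma, size=n_expr)
    if config.expression_noise:
        size_factor = rng.lognormal(0.0, config.libsize_sigma, size=n_cells)
    else:
        size_factor = np.ones(n_cells)
    in_a = np.array([cell_clone[c] in group_a_barcodes for c in cells])

    mean = mu_g[None, :] * size_factor[:, None]
    for gene_idx, group, fold in config.planted_de:
        rows = in_a if group == "a" else ~in_a
        mean[rows, gene_idx] = mean[rows, gene_idx] * fold

    if config.expression_noise:
        theta = config.nb_dispersion
        counts_expr = rng.negative_binomial(theta, theta / (theta + mean))
    else:
        counts_expr = np.round(mean).astype(np.int64)
    # guard against pathological zero-library cells
    empty = counts_expr.sum(axis=1) == 0
    counts_expr[empty, 0] = 1

    n_high = int(round(config.frac_high_mito * n_cells))
    high_idx = rng.choice(n_cells, size=n_high, replace=False)
    high_mask = np.zeros(n_cells, bool)
    high_mask[high_idx] = True
    if config.expression_noise:
        frac = np.clip(rng.beta(config.mito_beta_a, config.mito_beta_b,
                                size=n_cells), 0.0, 0.09)
        frac[high_mask] = rng.uniform(0.12, 0.35, size=n_high)
    else:  # noise-free: identical mito load everywhere
        frac = np.full(n_cells, 0.04)
        frac[high_mask] = 0.2

    nonmito_total = counts_expr.sum(axis=1)
    mito_total = np.round(frac / (1.0 - frac) * nonmito_total).astype(int)
    mito_counts = np.zeros((n_cells, n_mito), dtype=int)
    if config.expression_noise:
        mito_p = np.full(n_mito, 1.0 / n_mito)
        for i in range(n_cells):
            if mito_total[i] > 0:
                mito_counts[i] = rng.multinomial(mito_total[i], mito_p)
    else:
        base, rem = np.divmod(mito_total, n_mito)
        mito_counts[:] = base[:, None]
        for i in range(n_cells):
            mito_counts[i, :rem[i]] += 1

    X = np.hstack([mito_counts, counts_expr]).astype(np.int64)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"clone": [cell_clone[c] for c in cells]},
                         index=pd.Index(cells)),
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    return adata, [cells[i] for i in sorted(high_idx)]


def simulate_bridge_reads(
    cell_clone: dict[str, str],
    coverage: float,
    multimap_rate: float,
    rng: np.random.Generator,
    all_barcodes: list[str] | None = None,
    pad: int = 8,
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Long-read molecular bridges linking cell indexes to clone barcodes.

    A fraction ``coverage`` of cells emits one correct bridge read; of those,
    a fraction ``multimap_rate`` additionally emits a read naming a different
    clone barcode, which forces multimap exclusion downstream.  Returns
    (reads, covered cells, contaminated cells).
    """
    cells = sorted(cell_clone)
    barcodes = sorted(all_barcodes if all_barcodes is not None
                      else set(cell_clone.values()))
    covered = [c for c, u in zip(cells, rng.random(len(cells))) if u < coverage]
    reads: list[tuple[str, str]] = []
    contaminated: list[str] = []
    for i, cell in enumerate(covered):
        clone = cell_clone[cell]
        seq = (_random_seq(rng, pad) + cell + _random_seq(rng, pad)
               + clone + _random_seq(rng, pad))
        reads.append((f"bridge{i:06d}", seq))
        if rng.random() < multimap_rate and len(barcodes) > 1:
            wrong = clone
            while wrong == clone:
                wrong = barcodes[rng.integers(len(barcodes))]
            seq2 = (_random_seq(rng, pad) + cell + _random_seq(rng, pad)
                    + wrong + _random_seq(rng, pad))
            reads.append((f"bridge{i:06d}x", seq2))
            contaminated.append(cell)
    return reads, covered, contaminated


def simulate_serial_transplant(
    n_clones: int,
    n_passages: int,
    rng: np.random.Generator,
    expanding_frac: float = 0.4,
    fitness_separation: float = 4.0,
    fitness_sigma: float = 0.3,
    noise_sigma: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Clone abundance trajectories across transplant generations.

    Each clone carries a multiplicative per-passage fitness drawn from one of
    two log-normal modes (centred at ``fitness_separation`` and its
    reciprocal), emulating the two monotone trajectory families the
    transplant bottleneck selects for; abundances are renormalized to 100%
    per passage with a small log-normal bottleneck noise.  Truth class is the
    fitness mode: expanding or diminishing.  Returns (clones x passages %
    matrix, truth classes).
    """
    if n_passages < 2:
        raise ValueError("need >= 2 passages")
    a0 = rng.lognormal(0.0, 1.0, size=n_clones)
    expanding = rng.random(n_clones) < expanding_frac
    centre = np.where(expanding, np.log(fitness_separation),
                      -np.log(fitness_separation))
    fitness = rng.lognormal(centre, fitness_sigma)
    cols = {}
    a = a0.copy()
    for p in range(n_passages):
        if p > 0:
            a = a * fitness * rng.lognormal(0.0, noise_sigma, size=n_clones)
        cols[f"passage{p + 1}"] = 100.0 * a / a.sum()
    idx = pd.Index([f"clone{i + 1:03d}" for i in range(n_clones)], name="clone")
    traj = pd.DataFrame(cols, index=idx)
    classes = pd.Series(np.where(expanding, "expanding", "diminishing"),
                        index=idx, name="class")
    return traj, classes


def simulate_abundance_cohort(
    config: SimulationConfig,
) -> tuple[list, dict[str, SampleMeta], GroundTruth]:
    """Counts-only cohort for abundance statistics at scale.

    Same clone/tissue/FACS model as :func:`simulate_cohort`, but per-sample
    read counts are drawn directly from the multinomial instead of emitting
    read strings; returns (BarcodeCountTable list, metas, truth with empty
    single-cell fields).  Used where only the abundance matrix is needed.
    """
    from .barcode_quant import BarcodeCountTable

    rng = np.random.default_rng(config.seed)
    barcodes = random_barcodes(rng, config.n_clones, DEFAULT_BARCODE_LENGTH)
    biased_idx = list(range(config.n_biased_clones))
    base_sizes = rng.lognormal(config.clone_lognormal_mu,
                               config.clone_lognormal_sigma, size=config.n_clones)
    tables, metas, proportions, read_counts = [], {}, {}, {}
    for m in range(1, config.n_mice + 1):
        mouse_sizes = base_sizes * rng.lognormal(0.0, config.mouse_jitter_sigma,
                                                 size=config.n_clones)
        for tissue in config.tissues:
            sizes = mouse_sizes * rng.lognormal(
                0.0, config.tissue_noise_sigma, size=config.n_clones)
            if tissue == config.biased_tissue:
                sizes[biased_idx] *= config.bias_multiplier
            p = sizes / sizes.sum()
            counts = rng.multinomial(config.read_depth, p)
            sample_id = f"m{m}_{tissue}"
            tables.append(BarcodeCountTable(
                sample_id=sample_id,
                counts={barcodes[i]: int(counts[i]) for i in range(config.n_clones)
                        if counts[i] > 0}))
            proportions[sample_id] = {barcodes[i]: float(p[i])
                                      for i in range(config.n_clones)}
            read_counts[sample_id] = {barcodes[i]: int(counts[i])
                                      for i in range(config.n_clones)}
            mass_factor = float(sizes.sum() / mouse_sizes.sum())
            target_total = min(1.0, config.frac_human_of_mnc
                               * config.frac_gfp_of_human * mass_factor)
            frac_gfp = min(1.0, target_total / config.frac_human_of_mnc)
            metas[sample_id] = SampleMeta(
                sample_id=sample_id, mouse_id=f"m{m}", tissue=tissue,
                timepoint_days=28.0, treatment_arm="none", passage=1,
                frac_human_of_mnc=target_total / frac_gfp,
                frac_gfp_of_human=frac_gfp)
    truth = GroundTruth(
        clone_barcodes=barcodes, proportions=proportions,
        read_counts=read_counts, cell_clone={}, covered_cells=[],
        multimapped_cells=[], high_mito_cells=[], de_genes_up_in_a=[],
        de_genes_up_in_b=[], group_a_barcodes=[], group_b_barcodes=[],
        biased_clones=[barcodes[i] for i in biased_idx])
    return tables, metas, truth


def simulate_cohort(config: SimulationConfig, outdir=None) -> SimulatedCohort:
    """Full synthetic cohort: amplicon FASTQs, metadata, one 10x-style
    channel, bridge reads, and the ground truth; optionally written to
    ``outdir`` in exactly the formats the analysis modules consume."""
    rng = np.random.default_rng(config.seed)
    library = BarcodeLibrarySpec(DEFAULT_FLANK5, DEFAULT_FLANK3, DEFAULT_BARCODE_LENGTH)
    barcodes = random_barcodes(rng, config.n_clones, DEFAULT_BARCODE_LENGTH)

    biased_idx = list(range(config.n_biased_clones))
    biased = [barcodes[i] for i in biased_idx]
    if config.group_a_clones is not None:
        a_idx = set(config.group_a_clones)
    else:
        a_idx = set(range(config.n_clones // 2))
    group_a = [barcodes[i] for i in sorted(a_idx)]
    group_b = [barcodes[i] for i in range(config.n_clones) if i not in a_idx]

    base_sizes = rng.lognormal(config.clone_lognormal_mu,
                               config.clone_lognormal_sigma, size=config.n_clones)

    reads_per_sample: dict[str, list[tuple[str, str]]] = {}
    metas: dict[str, SampleMeta] = {}
    proportions: dict[str, dict[str, float]] = {}
    read_counts: dict[str, dict[str, int]] = {}
    for m in range(1, config.n_mice + 1):
        mouse_sizes = base_sizes * rng.lognormal(0.0, config.mouse_jitter_sigma,
                                                 size=config.n_clones)
        for tissue in config.tissues:
            # within-mouse biological variation between tissues; this, not
            # read-sampling noise, is what the blood-spleen band calibrates
            sizes = mouse_sizes * rng.lognormal(
                0.0, config.tissue_noise_sigma, size=config.n_clones)
            if tissue == config.biased_tissue:
                sizes[biased_idx] *= config.bias_multiplier
            p = sizes / sizes.sum()
            props = {barcodes[i]: float(p[i]) for i in range(config.n_clones)}
            sample_id = f"m{m}_{tissue}"
            reads, true_counts = simulate_barcode_reads(
                props, config.read_depth, library, rng,
                error_rate=config.barcode_error_rate, exact=config.exact_counts)
            reads_per_sample[sample_id] = reads
            proportions[sample_id] = props
            read_counts[sample_id] = true_counts
            # clonal expansion inflates the barcoded share of the tissue's
            # MNC: the sample's FACS fractions carry the total-mass factor,
            # so unbiased clones keep equal abundance (% of MNC) across
            # tissues, which is what the tissue-bias null assumes
            mass_factor = float(sizes.sum() / mouse_sizes.sum())
            target_total = min(1.0, config.frac_human_of_mnc
                               * config.frac_gfp_of_human * mass_factor)
            frac_gfp = min(1.0, target_total / config.frac_human_of_mnc)
            frac_human = target_total / frac_gfp
            metas[sample_id] = SampleMeta(
                sample_id=sample_id, mouse_id=f"m{m}", tissue=tissue,
                timepoint_days=28.0, treatment_arm="none", passage=1,
                frac_human_of_mnc=frac_human,
                frac_gfp_of_human=frac_gfp)

    # donor cells for the single-cell channel: cohort-level clone proportions
    p_cells = base_sizes / base_sizes.sum()
    cell_indexes = random_barcodes(rng, config.n_cells, CELL_INDEX_LENGTH)
    clone_of_cell_idx = rng.choice(config.n_clones, size=config.n_cells, p=p_cells)
    cell_clone = {cell_indexes[i]: barcodes[clone_of_cell_idx[i]]
                  for i in range(config.n_cells)}

    adata, high_mito = simulate_sc_counts(config, cell_clone, set(group_a), rng)
    bridges, covered, contaminated = simulate_bridge_reads(
        cell_clone, config.bridge_coverage, config.bridge_multimap_rate, rng,
        all_barcodes=barcodes)

    n_mito = config.n_mito_genes
    de_up_a = [adata.var_names[n_mito + g] for g, grp, f in config.planted_de
               if (grp == "a") == (f > 1)]
    de_up_b = [adata.var_names[n_mito + g] for g, grp, f in config.planted_de
               if (grp == "b") == (f > 1)]

    truth = GroundTruth(
        clone_barcodes=barcodes,
        proportions=proportions,
        read_counts=read_counts,
        cell_clone=cell_clone,
        covered_cells=covered,
        multimapped_cells=contaminated,
        high_mito_cells=high_mito,
        de_genes_up_in_a=sorted(de_up_a),
        de_genes_up_in_b=sorted(de_up_b),
        group_a_barcodes=group_a,
        group_b_barcodes=group_b,
        biased_clones=biased,
    )
    cohort = SimulatedCohort(config=config, library=library,
                             reads_per_sample=reads_per_sample, metas=metas,
                             adata=adata, bridge_reads=bridges, truth=truth)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


def balanced_clone_groups(barcodes: list[str], proportions: np.ndarray
                          ) -> tuple[list[str], list[str]]:
    """Greedy partition of clones into two groups of near-equal cell mass.

    Keeps both comparison groups adequately populated when cells are drawn
    in proportion to clone size.
    """
    order = np.argsort(-proportions, kind="stable")
    mass_a = mass_b = 0.0
    group_a, group_b = [], []
    for i in order:
        if mass_a <= mass_b:
            group_a.append(barcodes[i])
            mass_a += proportions[i]
        else:
            group_b.append(barcodes[i])
            mass_b += proportions[i]
    return sorted(group_a), sorted(group_b)


def simulate_mapped_dge_dataset(config: SimulationConfig):
    """Single-channel expression dataset with a fully mapped cell-clone
    truth, for differential-expression calibration studies.

    Clones are partitioned into two groups of near-equal expected cell mass;
    planted fold changes in ``config.planted_de`` apply to group "a"/"b"
    cells.  Returns (raw AnnData, CellCloneMap from truth, CloneGrouping
    with direction a_greater, truth planted-gene names).
    """
    from .bridge_map import CellCloneMap
    from .dge import CloneGrouping

    rng = np.random.default_rng(config.seed)
    barcodes = random_barcodes(rng, config.n_clones, DEFAULT_BARCODE_LENGTH)
    cells = random_barcodes(rng, config.n_cells, CELL_INDEX_LENGTH)
    sizes = rng.lognormal(config.clone_lognormal_mu,
                          config.clone_lognormal_sigma, size=config.n_clones)
    p = sizes / sizes.sum()
    group_a, group_b = balanced_clone_groups(barcodes, p)
    clone_idx = rng.choice(config.n_clones, size=config.n_cells, p=p)
    cell_clone = {cells[i]: barcodes[clone_idx[i]] for i in range(config.n_cells)}
    adata, _ = simulate_sc_counts(config, cell_clone, set(group_a), rng)
    ccmap = CellCloneMap(assignments=dict(cell_clone))
    grouping = CloneGrouping(frozenset(group_a), frozenset(group_b),
                             label="planted comparison", direction="a_greater")
    planted = [f"GENE{g + 1:04d}" for g, _, _ in config.planted_de]
    return adata, ccmap, grouping, planted
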