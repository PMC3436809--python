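"""Self-consistent synthetic eQTL cohorts with known ground truth.

The generator emulates the structure of a two-group eQTL study: a cohort
split into affected/unaffected patients, biallelic SNPs drawn per-locus
from Hardy-Weinberg proportions (independent SNPs, no LD), gene loci
tiling a synthetic chromosome, and gene expression that is Gaussian
noise plus optional *spiked* two-locus interaction effects
(``effect * codeA * codeB`` on a target gene).  Group-differential
genotype frequencies can be spiked as well: a *relevant* SNP's
non-reference allele frequency is shifted upward in the affected group.

The reference allele of each SNP is defined as the major allele of the
combined cohort (ties broken alphabetically), mirroring how a reference
table would be derived in practice.

Everything is a deterministic function of the config seed, and
:func:`generate_dataset` can write the six tab-separated input files the
readers in :mod:`eqtlnet.io` accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from .dialects import PLINK, Dialect
from .domain import (
    AFFECTED,
    UNAFFECTED,
    DataError,
    ExpressionMatrix,
    GeneLocus,
    GenotypeMatrix,
    PairResult,
    Patient,
    SingleLocusResult,
    SnpMeta,
)

#: PLINK's default --epi1 reporting threshold for epistasis output files
PLINK_EPI1 = 1e-4

_BASES = np.array(list("ACGT"))

GENE_SPAN = 60_000
GENE_PITCH = 100_000


@dataclass(frozen=True)
class SpikedPair:
    snp_a: str
    snp_b: str
    target_gene: str
    effect: float


@dataclass(frozen=True)
class SpikedRelevantSnp:
    snp_id: str
    shift: float  # added to the affected group's non-reference allele freq


@dataclass(frozen=True)
class SyntheticConfig:
    n_affected: int = 250
    n_unaffected: int = 250
    n_snps: int = 200
    n_genes: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    spiked_pairs: tuple[SpikedPair, ...] = ()
    spiked_relevant_snps: tuple[SpikedRelevantSnp, ...] = ()
    #: fixed minor-allele frequency of spiked causal SNPs (common variants,
    #: so the marginal effect is detectable at the default effect size)
    causal_maf: float = 0.4
    #: base non-reference frequency range for spiked relevant SNPs.  Kept
    #: below ~0.3 so the shifted group difference is visible to the
    #: three-state consensus summary: the summary is blind to q -> 1-q
    #: reflections (e.g. 0.4 -> 0.6 leaves the heterozygote fraction
    #: 2q(1-q) unchanged), so spiking inside that blind spot would make a
    #: SNP "relevant" in name only.
    relevant_base_range: tuple[float, float] = (0.1, 0.3)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_affected, self.n_unaffected, self.n_snps, self.n_genes) < 1:
            raise DataError("all cohort sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise DataError(f"invalid maf_range {self.maf_range}")

    @property
    def n_patients(self) -> int:
        return self.n_affected + self.n_unaffected


def snp_layout(n_snps: int, n_genes: int) -> tuple[list[SnpMeta], list[GeneLocus]]:
    """Deterministic layout: ``n_genes`` loci tile chromosome 1 and SNPs
    are distributed round-robin inside the loci."""
    loci = [GeneLocus(f"GENE{g:02d}", "1",
                      g * GENE_PITCH + 1, g * GENE_PITCH + GENE_SPAN)
            for g in range(n_genes)]
    per_gene = -(-n_snps // n_genes)  # ceil
    step = max(1, GENE_SPAN // (per_gene + 1))
    snps = []
    for k in range(n_snps):
        gene = k % n_genes
        slot = k // n_genes
        pos = loci[gene].start + (slot + 1) * step
        if pos > loci[gene].end:
            pos = loci[gene].end
        snps.append(SnpMeta(f"1:{pos}", "1", pos))
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        raise DataError("SNP layout produced duplicate positions; "
                        "reduce n_snps or increase the gene span")
    return snps, loci


@dataclass
class SyntheticDataset:
    """In-memory dataset plus the ground-truth manifest."""

    config: SyntheticConfig
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    patients: list[Patient]
    refs: dict[str, str]
    loci: list[GeneLocus]
    snp_meta: list[SnpMeta]
    codes: np.ndarray = field(repr=False, default=None)  # patients x snps

    @property
    def genes(self) -> list[str]:
        return [loc.gene for loc in self.loci]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for sp in self.config.spiked_pairs:
            rows.append({"TYPE": "interaction_pair", "SNP_A": sp.snp_a,
                         "SNP_B": sp.snp_b, "TARGET": sp.target_gene,
                         "VALUE": sp.effect})
        for sr in self.config.spiked_relevant_snps:
            rows.append({"TYPE": "relevant_snp", "SNP_A": sr.snp_id,
                         "SNP_B": "", "TARGET": "", "VALUE": sr.shift})
        return pd.DataFrame(rows,
                            columns=["TYPE", "SNP_A", "SNP_B", "TARGET", "VALUE"])

    def write(self, out_dir: str | Path, dialect: Dialect = PLINK) -> dict[str, Path]:
        """Write the six input files (+ truth manifest); returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        d = dialect
        paths = {name: out / f"{name}.tsv" for name in
                 ("genotypes", "expression", "phenotype", "reference",
                  "loci", "truth")}
        geno = self.genotypes.calls.fillna("00")
        geno.insert(0, d.patient_col, geno.index)
        geno.to_csv(paths["genotypes"], sep=d.sep, index=False)
        expr = self.expression.values.copy()
        expr.insert(0, d.gene_col, expr.index)
        expr.to_csv(paths["expression"], sep=d.sep, index=False,
                    float_format="%.10g")
        with open(paths["phenotype"], "w") as fh:
            fh.write(d.sep.join([d.family_col, d.patient_col, d.status_col]) + "\n")
            for p in self.patients:
                token = d.affected_token if p.group == AFFECTED else d.unaffected_token
                fh.write(d.sep.join([p.family_id, p.individual_id, token]) + "\n")
        with open(paths["reference"], "w") as fh:
            fh.write(d.sep.join([d.snp_col, d.base_col]) + "\n")
            for snp in self.genotypes.snps:
                fh.write(d.sep.join([snp, self.refs[snp]]) + "\n")
        with open(paths["loci"], "w") as fh:
            fh.write(d.sep.join([d.gene_col, d.chrom_col, d.start_col,
                                 d.end_col]) + "\n")
            for loc in self.loci:
                fh.write(d.sep.join([loc.gene, loc.chrom, str(loc.start),
                                     str(loc.end)]) + "\n")
        self.truth_table().to_csv(paths["truth"], sep=d.sep, index=False)
        return paths


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete dataset from the config's seed."""
    rng = np.random.default_rng(config.seed)
    snps, loci = snp_layout(config.n_snps, config.n_genes)
    gene_names = [loc.gene for loc in loci]
    causal_ids = {s for sp in config.spiked_pairs for s in (sp.snp_a, sp.snp_b)}
    shift_of = {sr.snp_id: sr.shift for sr in config.spiked_relevant_snps}
    known = {s.snp_id for s in snps}
    for sp in config.spiked_pairs:
        if sp.snp_a not in known or sp.snp_b not in known:
            raise DataError(f"spiked pair ({sp.snp_a}, {sp.snp_b}) references "
                            "an unknown SNP; use snp_layout() ids")
        if sp.target_gene not in gene_names:
            raise DataError(f"spiked target gene {sp.target_gene!r} unknown")
    for sid in shift_of:
        if sid not in known:
            raise DataError(f"spiked relevant SNP {sid!r} unknown")

    n_aff, n_unaff = config.n_affected, config.n_unaffected
    n = n_aff + n_unaff
    patients = (
        [Patient(f"F{i:04d}", f"P{i:04d}", AFFECTED) for i in range(n_aff)]
        + [Patient(f"F{i:04d}", f"P{i:04d}", UNAFFECTED)
           for i in range(n_aff, n)]
    )
    pids = [p.individual_id for p in patients]

    lo, hi = config.maf_range
    calls = np.empty((n, config.n_snps), dtype=object)
    codes = np.zeros((n, config.n_snps))
    refs: dict[str, str] = {}
    for j, snp in enumerate(snps):
        shift = shift_of.get(snp.snp_id, 0.0)
        if snp.snp_id in causal_ids:
            base_freq = config.causal_maf
        elif shift != 0.0:
            base_freq = float(rng.uniform(*config.relevant_base_range))
        else:
            base_freq = float(rng.uniform(lo, hi))
        q_aff = base_freq + shift
        if not 0.0 <= q_aff <= 1.0:
            raise DataError(
                f"SNP {snp.snp_id}: shifted frequency {q_aff:.3f} outside [0,1]"
            )
        allele_a, allele_b = rng.choice(_BASES, size=2, replace=False)
        counts = np.concatenate([
            rng.binomial(2, q_aff, size=n_aff),     # of allele_b
            rng.binomial(2, base_freq, size=n_unaff),
        ])
        # reference allele := major allele of the combined cohort
        n_b = int(counts.sum())
        if n_b > n:  # allele_b is the majority of the 2n observed alleles
            ref, alt = allele_b, allele_a
            non_ref = 2 - counts
        elif n_b < n:
            ref, alt = allele_a, allele_b
            non_ref = counts
        else:  # exact tie -> alphabetical
            ref, alt = sorted((allele_a, allele_b))
            non_ref = counts if ref == allele_a else 2 - counts
        refs[snp.snp_id] = str(ref)
        genos = {0: "".join(sorted(ref + ref)),
                 1: "".join(sorted(ref + alt)),
                 2: "".join(sorted(alt + alt))}
        calls[:, j] = [genos[int(c)] for c in non_ref]
        codes[:, j] = non_ref

    snp_index = {s.snp_id: j for j, s in enumerate(snps)}
    expr = rng.normal(0.0, config.noise_sd,
                      size=(config.n_genes, n)) if config.noise_sd > 0 \
        else np.zeros((config.n_genes, n))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for sp in config.spiked_pairs:
        ca = codes[:, snp_index[sp.snp_a]]
        cb = codes[:, snp_index[sp.snp_b]]
        expr[gene_index[sp.target_gene]] += sp.effect * ca * cb

    calls_df = pd.DataFrame(calls, index=pd.Index(pids, name="patient"),
                            columns=[s.snp_id for s in snps])
    expr_df = pd.DataFrame(expr, index=pd.Index(gene_names, name="gene"),
                           columns=pd.Index(pids, name="patient"))
    return SyntheticDataset(
        config=config,
        genotypes=GenotypeMatrix(calls_df),
        expression=ExpressionMatrix(expr_df),
        patients=patients,
        refs=refs,
        loci=loci,
        snp_meta=snps,
        codes=codes,
    )


def generate_result_files(
    dataset: SyntheticDataset,
    pairs: Optional[list[tuple[str, str]]] = None,
    epi1: Optional[float] = None,
    out_dir: Optional[str | Path] = None,
    dialect: Dialect = PLINK,
) -> tuple[list[SingleLocusResult], list[PairResult]]:
    """Run the mirror scans on a synthetic dataset and (optionally) write
    PLINK-style result files.

    ``pairs=None`` scans all unordered SNP pairs.  ``epi1`` mimics
    PLINK's --epi1 reporting threshold: only two-locus rows with
    p < epi1 are reported (``None`` reports every scanned row).
    """
    from .exprstats import single_locus_scan, two_locus_scan

    single = single_locus_scan(dataset.expression, dataset.genotypes,
                               dataset.refs)
    pair_results = two_locus_scan(dataset.expression, dataset.genotypes,
                                  dataset.refs, pairs=pairs)
    if epi1 is not None:
        pair_results = [r for r in pair_results if r.p < epi1]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_single_locus_results(single, out / "single_locus.tsv", dialect)
        eio.write_pair_results(pair_results, out / "two_locus.tsv", dialect)
    return single, pair_results


def default_study_config(
    seed: int,
    n_patients: int = 500,
    n_snps: int = 200,
    n_genes: int = 10,
    n_spiked_pairs: int = 3,
    n_spiked_relevant: int = 10,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    shift: float = 0.2,
) -> SyntheticConfig:
    """The package's reference study conditions: a balanced 500-patient
    cohort, 200 SNPs over 10 genes, 3 spiked trans interaction pairs and
    10 spiked group-differential SNPs.

    Spiked pairs are placed on distinct endpoint genes with a distinct
    target gene (trans effects); spiked relevant SNPs are drawn (seeded)
    from the remaining SNPs with a base frequency that keeps the shifted
    frequency inside [0, 1].
    """
    if n_genes < 2 * n_spiked_pairs + 1:
        raise DataError("need at least 2 genes per spiked pair plus a target")
    snps, loci = snp_layout(n_snps, n_genes)
    by_gene: dict[str, list[str]] = {loc.gene: [] for loc in loci}
    from .snpmap import assign_snps_to_genes

    smap = assign_snps_to_genes(snps, loci)
    for s in snps:
        by_gene[smap.gene_of(s.snp_id)].append(s.snp_id)
    genes = [loc.gene for loc in loci]
    spiked_pairs = []
    used: set[str] = set()
    for i in range(n_spiked_pairs):
        ga, gb = genes[2 * i], genes[2 * i + 1]
        target = genes[n_genes - 1 - i]
        a, b = by_gene[ga][0], by_gene[gb][0]
        spiked_pairs.append(SpikedPair(a, b, target, effect))
        used.update((a, b))
    rng = np.random.default_rng(seed)
    candidates = [s.snp_id for s in snps if s.snp_id not in used]
    chosen = rng.choice(len(candidates), size=n_spiked_relevant, replace=False)
    relevant = tuple(SpikedRelevantSnp(candidates[int(i)], shift)
                     for i in sorted(chosen))
    n_aff = n_patients // 2
    return SyntheticConfig(
        n_affected=n_aff,
        n_unaffected=n_patients - n_aff,
        n_snps=n_snps,
        n_genes=n_genes,
        maf_range=(0.1, 0.5),
        spiked_pairs=tuple(spiked_pairs),
        spiked_relevant_snps=relevant,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    """Outcome of the seeded end-to-end recovery study."""

    n_replicates: int
    edge_recovery_rate: float       # replicates where all spiked edges are heaviest
    edge_detection_rate: float      # replicates where all spiked edges are present
    relevant_sensitivity: float     # mean fraction of spiked relevant SNPs flagged
    relevant_false_positive_rate: float
    single_null_rejection_rate: float  # single-locus p<0.05 rate on null SNPs


def run_recovery_study(
    n_replicates: int = 50,
    base_seed: int = 1000,
    epi1: float = PLINK_EPI1,
    alpha: float = 0.05,
    r2_min: float = 0.1,
    p_max: float = 0.05,
    delta: float = 0.10,
    **config_kwargs,
) -> RecoveryResult:
    """Repeatedly simulate the reference study, run the full filter
    cascade and measure parameter recovery.

    Per replicate: the three spiked edges count as *recovered* when each
    is present in the cascade-filtered graph with weight at least the
    maximum weight among non-spiked edges.  Relevant-SNP sensitivity and
    false positive rate come from :func:`detect_relevant_snps` over all
    SNPs.
    """
    from .genotype import detect_relevant_snps, summarize_all
    from .network import (
        build_association_graph,
        restrict_pairs_to_snp_set,
        significant_single_locus_snps,
    )
    from .snpmap import assign_snps_to_genes

    edge_ok = 0
    edge_present = 0
    sens_sum = 0.0
    fp_sum = 0.0
    null_rej_sum = 0.0
    for rep in range(n_replicates):
        cfg = default_study_config(seed=base_seed + rep, **config_kwargs)
        ds = generate_dataset(cfg)
        single, pair_results = generate_result_files(ds, epi1=epi1)
        smap = assign_snps_to_genes(ds.snp_meta, ds.loci)
        keep = significant_single_locus_snps(single, r2_min=r2_min, p_max=p_max)
        restricted = restrict_pairs_to_snp_set(pair_results, keep)
        graph = build_association_graph(restricted, smap, ds.genes, alpha=alpha)
        weights = graph.weights()
        spiked_keys = {
            (tuple(sorted((smap.gene_of(sp.snp_a), smap.gene_of(sp.snp_b)))),
             sp.target_gene)
            for sp in cfg.spiked_pairs
        }
        spiked_w = [weights.get(k, 0) for k in spiked_keys]
        other_w = [w for k, w in weights.items() if k not in spiked_keys]
        max_other = max(other_w, default=0)
        if all(w > 0 for w in spiked_w):
            edge_present += 1
            if min(spiked_w) >= max_other:
                edge_ok += 1

        summaries = summarize_all(ds.genotypes, ds.patients, ds.refs)
        relevant = detect_relevant_snps(summaries, delta=delta)
        spiked_rel = {sr.snp_id for sr in cfg.spiked_relevant_snps}
        n_rel = len(spiked_rel)
        sens_sum += len(relevant & spiked_rel) / n_rel if n_rel else 1.0
        null_snps = set(ds.genotypes.snps) - spiked_rel
        fp_sum += len(relevant & null_snps) / len(null_snps)

        causal = {s for sp in cfg.spiked_pairs for s in (sp.snp_a, sp.snp_b)}
        null_p = [r.p for r in single if r.snp_id not in causal]
        null_rej_sum += float(np.mean([p < 0.05 for p in null_p]))
    return RecoveryResult(
        n_replicates=n_replicates,
        edge_recovery_rate=edge_ok / n_replicates,
        edge_detection_rate=edge_present / n_replicates,
        relevant_sensitivity=sens_sum / n_replicates,
        relevant_false_positive_rate=fp_sum / n_replicates,
        single_null_rejection_rate=null_rej_sum / n_replicates,
    )
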