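"""Synthetic three-library grazing experiment with known planted truth.

Emulates the study design: three unreplicated whole-plant RNA bulks —
tolerant ungrazed (TU), tolerant grazed (TG) and intolerant grazed (IG) —
with Poisson count noise around FPKM-derived means, planted log2 effects for
both contrasts, isoform groups, annotation maps with planted enriched terms,
transcript sequences with planted per-sample SNPs, and two-group phenotype
traits. Every planted quantity is returned in a :class:`TruthSet` so each
pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    CountTable,
    TranscriptSeq,
    write_annotation,
    write_count_table,
    write_fasta_with_cds,
    write_isoform_groups,
)
from .patterns import OTHER, SUPPRESSED, UPREGULATED

__all__ = [
    "OntologySpec",
    "SnpSpec",
    "PhenotypeSpec",
    "SimulationConfig",
    "TruthSet",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_phenotypes",
    "write_fixture",
]

SAMPLES = ("TU", "TG", "IG")
ROLES = {
    "tolerant_ungrazed": "TU",
    "tolerant_grazed": "TG",
    "intolerant_grazed": "IG",
}


@dataclass
class OntologySpec:
    """Shape of one synthetic annotation ontology."""

    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 80)
    n_enriched: int = 5
    enriched_de_members: int = 15  # both-contrast DE genes added per planted term
    annotated_fraction: float = 0.9


@dataclass
class SnpSpec:
    """Planted SNP sites and decoys for the consistency filter."""

    n_consistent: int = 10
    n_decoys_per_class: int = 4
    coverage_range: tuple[int, int] = (30, 80)
    error_rate: float = 0.01


@dataclass
class PhenotypeSpec:
    """Two-group trait parameters (tolerant vs intolerant, n per group)."""

    traits: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: {
            "shoot_canopy_area": ((9669.70, 5890.62), (602.60, 249.45)),
            "basal_plant_diameter": ((13.95, 2.26), (7.45, 1.57)),
            "shoot_height": ((79.70, 9.90), (30.80, 11.25)),
            "stem_number": ((72.70, 14.77), (23.00, 12.12)),
        }
    )
    n_per_group: int = 10


@dataclass
class SimulationConfig:
    """Study-scale defaults: 2,000 genes, three libraries of 2e6 clean reads."""

    n_genes: int = 2000
    isoforms_range: tuple[int, int] = (1, 4)
    length_range: tuple[int, int] = (300, 3000)
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {s: 2_000_000 for s in SAMPLES}
    )
    fpkm_log_mean: float = 2.0
    fpkm_log_sd: float = 1.0
    planted_lfc: float = 2.0
    n_suppressed: int = 10
    n_upregulated: int = 10
    frac_de_response: float = 0.08
    frac_de_tolerance: float = 0.05
    frac_de_both: float = 0.03
    pattern_min_expected_count: int = 40
    ontologies: dict[str, OntologySpec] = field(
        default_factory=lambda: {"GO": OntologySpec(), "KEGG": OntologySpec(n_terms=30)}
    )
    snps: SnpSpec = field(default_factory=SnpSpec)
    phenotypes: PhenotypeSpec = field(default_factory=PhenotypeSpec)

    def validate(self) -> None:
        n_planted = self.n_suppressed + self.n_upregulated
        n_de = int(
            self.n_genes * (self.frac_de_response + self.frac_de_tolerance + self.frac_de_both)
        )
        if n_planted + n_de > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")
        for frac in (self.frac_de_response, self.frac_de_tolerance, self.frac_de_both):
            if not 0 <= frac <= 1:
                raise ValueError("DE fractions must lie in [0, 1]")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")


@dataclass
class TruthSet:
    """Planted ground truth for every pipeline stage."""

    transcripts: pd.DataFrame       # expected FPKM triple, true lfc and DE per contrast
    gene_patterns: dict[str, str]   # gene_id -> pattern (incl. "other")
    enriched_terms: dict[str, list[str]]  # ontology -> planted term ids
    snps: pd.DataFrame              # planted sites with class and expected_keep
    phenotypes: PhenotypeSpec


@dataclass
class SimulatedExperiment:
    counts: CountTable
    groups: dict[str, str]
    annotations: dict[str, AnnotationMap]
    sequences: dict[str, TranscriptSeq]
    base_composition: pd.DataFrame
    truth: TruthSet
    roles: dict[str, str] = field(default_factory=lambda: dict(ROLES))


def _gene_effects(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign per-gene log2 effects for the two contrasts and the true pattern."""
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    lfc = cfg.planted_lfc
    eff_resp = np.zeros(cfg.n_genes)
    eff_tol = np.zeros(cfg.n_genes)
    pattern = np.full(cfg.n_genes, OTHER, dtype=object)
    i = 0
    sup = order[i : i + cfg.n_suppressed]; i += cfg.n_suppressed
    up = order[i : i + cfg.n_upregulated]; i += cfg.n_upregulated
    n_r = int(cfg.n_genes * cfg.frac_de_response)
    n_t = int(cfg.n_genes * cfg.frac_de_tolerance)
    n_b = int(cfg.n_genes * cfg.frac_de_both)
    resp_only = order[i : i + n_r]; i += n_r
    tol_only = order[i : i + n_t]; i += n_t
    both = order[i : i + n_b]; i += n_b
    eff_resp[sup], eff_tol[sup] = -lfc, -lfc
    pattern[sup] = SUPPRESSED
    eff_resp[up], eff_tol[up] = lfc, -lfc
    pattern[up] = UPREGULATED
    eff_resp[resp_only] = rng.choice([-lfc, lfc], size=n_r)
    # decoy classes: tolerance effect positive (intolerant higher), so no
    # tolerant-advantage pattern arises outside the planted gene sets
    eff_tol[tol_only] = lfc
    eff_resp[both] = rng.choice([-lfc, lfc], size=n_b)
    eff_tol[both] = lfc
    return genes, eff_resp, eff_tol, pattern


def simulate_experiment(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedExperiment:
    """Draw one full synthetic experiment; byte-identical for a fixed seed."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes, eff_resp, eff_tol, gene_pattern = _gene_effects(cfg, rng)

    lib = cfg.library_sizes
    min_lib = min(lib.values())
    rows = []
    groups: dict[str, str] = {}
    for gi, gene in enumerate(genes):
        n_iso = int(rng.integers(cfg.isoforms_range[0], cfg.isoforms_range[1] + 1))
        for j in range(n_iso):
            tid = f"{gene}.t{j + 1}"
            groups[tid] = gene
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            base_fpkm = float(rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sd))
            mult = {
                "TU": 1.0,
                "TG": 2.0 ** eff_resp[gi],
                "IG": 2.0 ** (eff_resp[gi] + eff_tol[gi]),
            }
            if gene_pattern[gi] != OTHER:
                # guarantee detection margin: weakest library still yields a
                # well-measured count for planted candidate genes
                floor = cfg.pattern_min_expected_count / (
                    min(mult.values()) * (length / 1e3) * (min_lib / 1e6)
                )
                base_fpkm = max(base_fpkm, floor)
            fpkm = {s: base_fpkm * mult[s] for s in SAMPLES}
            rows.append(
                (
                    tid, gene, length,
                    fpkm["TU"], fpkm["TG"], fpkm["IG"],
                    eff_resp[gi], eff_tol[gi],
                    eff_resp[gi] != 0, eff_tol[gi] != 0,
                )
            )
    truth_tx = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "length_bp",
            "fpkm_tu", "fpkm_tg", "fpkm_ig",
            "lfc_response", "lfc_tolerance",
            "de_response", "de_tolerance",
        ],
    )
    lam = {
        s: truth_tx[f"fpkm_{s.lower()}"].to_numpy()
        * (truth_tx["length_bp"].to_numpy() / 1e3)
        * (lib[s] / 1e6)
        for s in SAMPLES
    }
    counts = pd.DataFrame(
        {s: rng.poisson(lam[s]) for s in SAMPLES},
        index=pd.Index(truth_tx["transcript_id"], name="transcript_id"),
    )
    table = CountTable(
        counts=counts,
        lengths=pd.Series(
            truth_tx["length_bp"].to_numpy(),
            index=counts.index, name="length_bp",
        ),
        totals=dict(lib),
    )

    annotations, enriched = _simulate_annotations(cfg, rng, genes, eff_resp, eff_tol, gene_pattern)
    sequences, base_comp, truth_snps = _simulate_snps(cfg, rng, truth_tx, gene_pattern, genes)

    truth = TruthSet(
        transcripts=truth_tx,
        gene_patterns={g: gene_pattern[i] for i, g in enumerate(genes)},
        enriched_terms=enriched,
        snps=truth_snps,
        phenotypes=cfg.phenotypes,
    )
    return SimulatedExperiment(
        counts=table,
        groups=groups,
        annotations=annotations,
        sequences=sequences,
        base_composition=base_comp,
        truth=truth,
    )


def _simulate_annotations(cfg, rng, genes, eff_resp, eff_tol, gene_pattern):
    """Build per-ontology annotation maps with planted over-represented terms.

    Planted terms contain every candidate-pattern gene plus extra genes that
    are DE in both contrasts, so the terms are enriched in both the response
    and the tolerance DEG sets.
    """
    pattern_genes = [g for g, p in zip(genes, gene_pattern) if p != OTHER]
    both_de = [
        g
        for g, r, t, p in zip(genes, eff_resp, eff_tol, gene_pattern)
        if r != 0 and t != 0 and p == OTHER
    ]
    annotations: dict[str, AnnotationMap] = {}
    enriched: dict[str, list[str]] = {}
    for name, spec in cfg.ontologies.items():
        n_univ = int(round(spec.annotated_fraction * len(genes)))
        universe = set(rng.choice(genes, size=n_univ, replace=False))
        universe.update(pattern_genes)
        universe.update(both_de)
        univ_list = sorted(universe)
        terms: dict[str, frozenset[str]] = {}
        planted: list[str] = []
        for t in range(spec.n_terms):
            term_id = f"{name}:{t:04d}"
            size = int(rng.integers(spec.term_size_range[0], spec.term_size_range[1] + 1))
            if t < spec.n_enriched:
                extra = list(
                    rng.choice(both_de, size=min(spec.enriched_de_members, len(both_de)), replace=False)
                )
                members = set(pattern_genes) | set(extra)
                n_bg = max(0, size - len(members))
                members |= set(rng.choice(univ_list, size=n_bg, replace=False))
                planted.append(term_id)
            else:
                members = set(rng.choice(univ_list, size=min(size, len(univ_list)), replace=False))
            terms[term_id] = frozenset(members)
        annotations[name] = AnnotationMap(name=name, terms=terms, universe=frozenset(universe))
        enriched[name] = planted
    return annotations, enriched


_DECOY_CLASSES = (
    "tolerant_discordant",      # grazed tolerant heterozygous, ungrazed not
    "all_identical_het",        # same ambiguity code in all three libraries
    "all_identical_mono",       # same single base everywhere
    "intolerant_no_coverage",   # intolerant library uncovered at the site
)


def _simulate_snps(cfg, rng, truth_tx, gene_pattern, genes):
    """Plant consistent SNPs and one decoy per violation class of the filter."""
    spec = cfg.snps
    pattern_tids = truth_tx.loc[
        truth_tx["gene_id"].isin({g for g, p in zip(genes, gene_pattern) if p != OTHER}),
        ["transcript_id", "length_bp"],
    ]
    other_tids = truth_tx.loc[
        ~truth_tx["transcript_id"].isin(pattern_tids["transcript_id"]),
        ["transcript_id", "length_bp"],
    ]
    n_sites = spec.n_consistent + spec.n_decoys_per_class * len(_DECOY_CLASSES)
    hosts = pd.concat([pattern_tids, other_tids]).head(max(n_sites, len(pattern_tids)))
    host_rows = hosts.reset_index(drop=True)
    bases = np.array(list("ACGT"))
    sequences: dict[str, TranscriptSeq] = {}
    comp_rows = []
    truth_rows = []

    site_classes = ["consistent"] * spec.n_consistent
    for cls in _DECOY_CLASSES:
        site_classes += [cls] * spec.n_decoys_per_class
    for k, cls in enumerate(site_classes):
        host = host_rows.iloc[k % len(host_rows)]
        tid, length = host["transcript_id"], int(host["length_bp"])
        if tid not in sequences:
            seq = "".join(rng.choice(bases, size=length))
            if k % 7 == 6:
                cds = None  # keep some noncoding transcripts in play
            else:
                utr5 = int(rng.integers(30, max(31, length // 10)))
                max_cds = ((length - utr5 - 30) // 3) * 3
                cds_len = min(max_cds, 3 * int(rng.integers(30, 200)))
                cds = (utr5 + 1, utr5 + cds_len)
            sequences[tid] = TranscriptSeq(tid, seq, cds)
        ts = sequences[tid]
        used = {r[1] for r in truth_rows if r[0] == tid}
        pos = int(rng.integers(1, length + 1))
        while pos in used:
            pos = int(rng.integers(1, length + 1))
        ref = ts.sequence[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        het = [ref, alt]
        if cls == "consistent":
            ig_geno = het if k % 2 == 0 else [alt]
            geno = {"TU": [ref], "TG": [ref], "IG": ig_geno}
            expected_keep = True
        elif cls == "tolerant_discordant":
            geno = {"TU": [ref], "TG": het, "IG": [alt]}
            expected_keep = False
        elif cls == "all_identical_het":
            geno = {"TU": het, "TG": het, "IG": het}
            expected_keep = False
        elif cls == "all_identical_mono":
            geno = {"TU": [ref], "TG": [ref], "IG": [ref]}
            expected_keep = False
        else:  # intolerant_no_coverage
            geno = {"TU": [ref], "TG": [ref], "IG": None}
            expected_keep = False
        for sample in SAMPLES:
            alleles = geno[sample]
            if alleles is None:
                continue
            cov = int(rng.integers(spec.coverage_range[0], spec.coverage_range[1] + 1))
            # each read draws a true allele uniformly, then miscalls to one of
            # the three other bases with probability error_rate
            e, k = spec.error_rate, len(alleles)
            probs = np.zeros(4)
            for b in range(4):
                for a in alleles:
                    probs[b] += (1 / k) * ((1 - e) if "ACGT"[b] == a else e / 3)
            draw = rng.multinomial(cov, probs)
            comp_rows.append((tid, pos, sample, *draw.tolist()))
        truth_rows.append((tid, pos, ref, alt, cls, expected_keep))
    base_comp = pd.DataFrame(
        comp_rows, columns=["transcript_id", "pos", "sample", "nA", "nC", "nG", "nT"]
    )
    truth_snps = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "pos", "ref", "alt", "snp_class", "expected_keep"],
    )
    return sequences, base_comp, truth_snps


def simulate_phenotypes(config: SimulationConfig | PhenotypeSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw two-group trait values (normal, per-trait means/SDs, n per group)."""
    if config is None:
        spec = PhenotypeSpec()
    elif isinstance(config, SimulationConfig):
        spec = config.phenotypes
    else:
        spec = config
    if spec.n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    rows = []
    for trait, ((m1, s1), (m2, s2)) in spec.traits.items():
        for v in rng.normal(m1, s1, size=spec.n_per_group):
            rows.append((trait, "tolerant", float(v)))
        for v in rng.normal(m2, s2, size=spec.n_per_group):
            rows.append((trait, "intolerant", float(v)))
    return pd.DataFrame(rows, columns=["trait", "group", "value"])


def write_fixture(exp: SimulatedExperiment, outdir: str | Path, phenotypes: pd.DataFrame | None = None) -> None:
    """Write the full input surface of one experiment as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(exp.counts, out / "counts.tsv")
    write_isoform_groups(exp.groups, out / "groups.tsv")
    for name, ann in exp.annotations.items():
        write_annotation(ann, out / f"annotation_{name.lower()}.tsv")
    write_fasta_with_cds(exp.sequences, out / "transcripts.fasta", out / "cds.tsv")
    exp.base_composition.to_csv(out / "basecomp.tsv", sep="\t", index=False)
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    truth = {
        "gene_patterns": exp.truth.gene_patterns,
        "enriched_terms": exp.truth.enriched_terms,
        "roles": exp.roles,
        "phenotypes": asdict(exp.truth.phenotypes),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    exp.truth.transcripts.to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)
    exp.truth.snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
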