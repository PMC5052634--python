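"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: per
subject, heterozygous SNPs inside genes; per sample (subject x tissue),
binomially sampled allele read counts with a null allele fraction of 0.5;
and a gene x sample expression matrix with tissue-group structure. Four
event classes can be injected with full truth labels:

* extreme ASE — one haplotype of a gene over-expressed in one subject,
* imprinting — one parental allele silenced cohort-wide with a penetrance,
* NMD — the haplotype carrying a nonsense variant under-expressed,
* biallelic LOE — a gene's expression knocked down by a fold in one subject,

plus mapping-bias contamination (artifactual monoallelic reference
expression with positional QC flags), so every filter has something to find.

Haplotype bookkeeping: each SNP records whether its ALT base sits on
haplotype 1; haplotype 1 is the maternal haplotype for trio-phased
subjects. Within a gene all event SNPs place the over-expressed base on
one haplotype — the assumption the unphased higher-allele heuristic
exploits — while null SNPs randomise which base is higher.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from aseloe import io as aio
from aseloe.io import ExpressionTable, GeneModel

__all__ = [
    "AseEvent", "ImprintingEvent", "NmdEvent", "LoeEvent",
    "SimulationConfig", "SyntheticCohort",
    "generate_cohort", "inject_mapping_bias", "subsample_snps",
    "gene_base_means", "gene_category_flags", "study_config",
    "f1_validation_config", "strong_events_config", "null_config",
    "write_cohort", "load_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AseEvent:
    gene: int          # gene index
    subject: int       # subject index (cases first, then controls)
    allele_fraction: float  # fraction of reads from the over-expressed haplotype
    #: total-expression fold relative to baseline; 1.0 models dosage
    #: compensation, ~0.5 an uncompensated silenced allele, >1 allele gain.
    expression_fold: float = 1.0


@dataclass(frozen=True)
class ImprintingEvent:
    gene: int
    expressed_parent: str  # "maternal" or "paternal"
    penetrance: float = 1.0


@dataclass(frozen=True)
class NmdEvent:
    gene: int
    subject: int
    lof_allele_fraction: float = 0.1  # read share of the LOF-carrying haplotype


@dataclass(frozen=True)
class LoeEvent:
    gene: int
    subject: int
    fold: float = 0.1


@dataclass
class SimulationConfig:
    """Cohort geometry, sampling model, and events to inject.

    Defaults give the scaled study size (200 genes x 24 subjects x 2
    tissues) so that the full pipeline runs in seconds. Allele counts are
    pure binomial by default; ``overdispersion_rho`` switches on a
    beta-binomial for robustness studies (the analysis model itself is
    binomial, so this stays off).
    """

    n_subjects: int = 12
    n_controls: int = 12
    tissues_per_subject: int = 2
    n_genes: int = 200
    snps_per_gene_mean: float = 3.0
    read_depth_mean: float = 60.0
    null_allele_fraction: float = 0.5
    ase_events: tuple = ()
    imprinting_events: tuple = ()
    nmd_events: tuple = ()
    loe_events: tuple = ()
    #: (gene, subject) pairs given a nonsense het SNP with null (no-decay)
    #: expression; these populate the denominator of the NMD fraction.
    lof_backgrounds: tuple = ()
    mapping_bias_fraction: float = 0.0
    trio_fraction: float = 0.25
    seed: int = 0
    # sampling model knobs
    overdispersion_rho: float = 0.0
    imprint_expressed_fraction: float = 0.95
    expr_mu_log: float = 3.4        # log mean of gene base expression (r.p.m.)
    expr_sigma_log: float = 1.2     # between-gene spread
    expr_tissue_sigma: float = 0.15  # gene x tissue structure
    expr_noise_cv: float = 0.2      # within-tissue-group sample noise
    total_reads_per_sample: int = 2_000_000
    fetal_low_fraction: float = 0.05
    noncoding_fraction: float = 0.03
    alt_exon_fraction: float = 0.10

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects, "n_controls": self.n_controls,
            "tissues_per_subject": self.tissues_per_subject, "n_genes": self.n_genes,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive count, got {v!r}")
        probs = {
            "null_allele_fraction": self.null_allele_fraction,
            "mapping_bias_fraction": self.mapping_bias_fraction,
            "trio_fraction": self.trio_fraction,
            "overdispersion_rho": self.overdispersion_rho,
            "imprint_expressed_fraction": self.imprint_expressed_fraction,
            "fetal_low_fraction": self.fetal_low_fraction,
            "noncoding_fraction": self.noncoding_fraction,
            "alt_exon_fraction": self.alt_exon_fraction,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v!r}")
        if self.snps_per_gene_mean <= 0:
            raise ValueError(f"snps_per_gene_mean must be positive, got {self.snps_per_gene_mean!r}")
        if self.read_depth_mean <= 0:
            raise ValueError(f"read_depth_mean must be positive, got {self.read_depth_mean!r}")
        n_total = self.n_subjects + self.n_controls
        for kind, events in (("ase_events", self.ase_events), ("nmd_events", self.nmd_events),
                             ("loe_events", self.loe_events), ("lof_backgrounds", self.lof_backgrounds)):
            for ev in events:
                gene = ev[0] if isinstance(ev, tuple) else ev.gene
                subj = ev[1] if isinstance(ev, tuple) else ev.subject
                if not (0 <= gene < self.n_genes):
                    raise ValueError(f"{kind}: gene index {gene} out of range")
                if not (0 <= subj < n_total):
                    raise ValueError(f"{kind}: subject index {subj} out of range")
        for ev in self.imprinting_events:
            if not (0 <= ev.gene < self.n_genes):
                raise ValueError(f"imprinting_events: gene index {ev.gene} out of range")
            if ev.expressed_parent not in ("maternal", "paternal"):
                raise ValueError(f"imprinting_events: bad expressed_parent {ev.expressed_parent!r}")
            if not (0.0 <= ev.penetrance <= 1.0):
                raise ValueError(f"imprinting_events: penetrance must be in [0,1], got {ev.penetrance!r}")
        for ev in self.ase_events:
            if not (0.0 <= ev.allele_fraction <= 1.0):
                raise ValueError(f"ase_events: allele_fraction must be in [0,1], got {ev.allele_fraction!r}")
            if ev.expression_fold <= 0:
                raise ValueError(f"ase_events: expression_fold must be positive, got {ev.expression_fold!r}")
        for ev in self.nmd_events:
            if not (0.0 <= ev.lof_allele_fraction <= 0.5):
                raise ValueError(f"nmd_events: lof_allele_fraction must be in [0,0.5], got {ev.lof_allele_fraction!r}")
        for ev in self.loe_events:
            if not (0.0 <= ev.fold <= 1.0):
                raise ValueError(f"loe_events: fold must be in [0,1], got {ev.fold!r}")
        ase_keys = {(e.gene, e.subject) for e in self.ase_events}
        loe_keys = {(e.gene, e.subject) for e in self.loe_events}
        overlap = ase_keys & loe_keys
        if overlap:
            raise ValueError(f"ase_events/loe_events: gene,subject pairs in both: {sorted(overlap)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ase_events", "imprinting_events", "nmd_events", "loe_events", "lof_backgrounds"):
            d[key] = [
                list(dataclasses.astuple(e)) if dataclasses.is_dataclass(e) else list(e)
                for e in getattr(self, key)
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["ase_events"] = tuple(
            AseEvent(int(e[0]), int(e[1]), float(e[2]), float(e[3]) if len(e) > 3 else 1.0)
            for e in d.get("ase_events", ()))
        d["imprinting_events"] = tuple(
            ImprintingEvent(int(g), str(p), float(q)) for g, p, q in d.get("imprinting_events", ()))
        d["nmd_events"] = tuple(NmdEvent(int(g), int(s), float(f)) for g, s, f in d.get("nmd_events", ()))
        d["loe_events"] = tuple(LoeEvent(int(g), int(s), float(f)) for g, s, f in d.get("loe_events", ()))
        d["lof_backgrounds"] = tuple((int(g), int(s)) for g, s in d.get("lof_backgrounds", ()))
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated genotypes, allele counts, expression and truth labels."""

    config: SimulationConfig
    snps: pd.DataFrame            # io.SNP_COLUMNS plus alt_on_hap1 (truth phase)
    allele_counts: pd.DataFrame   # io.COUNT_COLUMNS
    expression: ExpressionTable
    gene_models: list
    fetal_reference: pd.Series
    imprint_catalog: pd.DataFrame
    truth: dict                   # event-class name -> DataFrame
    indels: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["subject_id", "chrom", "pos"]))
    cohort_of: dict = field(default_factory=dict)  # subject_id -> "case"/"control"

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            config=self.config,
            snps=self.snps.copy(),
            allele_counts=self.allele_counts.copy(),
            expression=ExpressionTable(self.expression.counts.copy(), self.expression.samples.copy()),
            gene_models=list(self.gene_models),
            fetal_reference=self.fetal_reference.copy(),
            imprint_catalog=self.imprint_catalog.copy(),
            truth={k: v.copy() for k, v in self.truth.items()},
            indels=self.indels.copy(),
            cohort_of=dict(self.cohort_of),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def gene_base_means(n_genes: int, seed: int, mu_log: float = 3.4, sigma_log: float = 1.2) -> np.ndarray:
    """Deterministic per-gene baseline expression (r.p.m.), log-normal.

    Exposed so callers can place injected events on genes of known
    expression class (e.g., upper-quartile genes for LOE) before generating
    the cohort.
    """
    rng = np.random.default_rng([int(seed) % 2**31, 101])
    return rng.lognormal(mean=mu_log, sigma=sigma_log, size=n_genes)


def gene_category_flags(
    n_genes: int, seed: int,
    noncoding_fraction: float, fetal_low_fraction: float, alt_exon_fraction: float,
) -> tuple:
    """Deterministic (noncoding, fetal_low, has_alt_exon) masks per gene.

    Drawn from their own stream so event placement (which must avoid genes
    the category filters remove) can see them before cohort generation.
    """
    rng = np.random.default_rng([int(seed) % 2**31, 31])
    noncoding = rng.random(n_genes) < noncoding_fraction
    fetal_low = rng.random(n_genes) < fetal_low_fraction
    alt_exon = rng.random(n_genes) < alt_exon_fraction
    return noncoding, fetal_low, alt_exon


def _subject_ids(cfg: SimulationConfig) -> list[str]:
    cases = [f"case{i + 1:03d}" for i in range(cfg.n_subjects)]
    ctrls = [f"ctrl{i + 1:03d}" for i in range(cfg.n_controls)]
    return cases + ctrls


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng([int(cfg.seed) % 2**31, 7])

    subjects = _subject_ids(cfg)
    n_total = len(subjects)
    cohort_of = {s: ("case" if i < cfg.n_subjects else "control") for i, s in enumerate(subjects)}
    tissues = [f"tissue{t + 1}" for t in range(cfg.tissues_per_subject)]

    # --- gene models: fixed candidate SNP sites shared across subjects ----
    base_means = gene_base_means(cfg.n_genes, cfg.seed, cfg.expr_mu_log, cfg.expr_sigma_log)
    n_sites = max(4, int(np.ceil(cfg.snps_per_gene_mean * 2)))
    het_p = min(0.95, cfg.snps_per_gene_mean / n_sites)  # per-site het probability
    imprint_parent = {ev.gene: ev.expressed_parent for ev in cfg.imprinting_events}

    genes: list[GeneModel] = []
    site_pos = np.zeros((cfg.n_genes, n_sites), dtype=int)
    site_ref = np.empty((cfg.n_genes, n_sites), dtype=object)
    site_alt = np.empty((cfg.n_genes, n_sites), dtype=object)
    site_alt_exon = np.zeros((cfg.n_genes, n_sites), dtype=bool)
    noncoding, fetal_low, has_alt_exon = gene_category_flags(
        cfg.n_genes, cfg.seed, cfg.noncoding_fraction, cfg.fetal_low_fraction,
        cfg.alt_exon_fraction)
    for g in range(cfg.n_genes):
        chrom = f"chr{g % 22 + 1}"
        start = 1_000_000 * (g // 22 + 1) + 1
        main_end = start + 100 * (n_sites + 2)
        exons = [(start, main_end, ("iso1", "iso2"))]
        positions = start + 100 * (1 + np.arange(n_sites))
        alt_exon_mask = np.zeros(n_sites, dtype=bool)
        if has_alt_exon[g]:
            # last candidate site moves into an exon private to iso1
            exons.append((main_end + 200, main_end + 500, ("iso1",)))
            positions = positions.copy()
            positions[-1] = main_end + 300
            alt_exon_mask[-1] = True
        refs = rng.choice(_BASES, size=n_sites)
        alts = np.array([rng.choice([b for b in _BASES if b != r]) for r in refs])
        site_pos[g], site_ref[g], site_alt[g], site_alt_exon[g] = positions, refs, alts, alt_exon_mask
        genes.append(GeneModel(
            gene_id=f"GENE{g + 1:04d}", gene_symbol=f"GENE{g + 1:04d}",
            chrom=chrom, strand=rng.choice(["+", "-"]), exons=tuple(exons),
            coding_flag=not noncoding[g],
            known_imprinted=imprint_parent.get(g),
        ))
    gene_ids = [g.gene_id for g in genes]

    fetal = pd.Series(base_means, index=gene_ids, name="fetal_rpm")
    fetal = fetal.where(~fetal_low, 0.5)

    # --- event lookups ---------------------------------------------------
    ase_by_key = {(e.gene, e.subject): e for e in cfg.ase_events}
    nmd_by_key = {(e.gene, e.subject): e for e in cfg.nmd_events}
    lof_bg = set((int(g), int(s)) for g, s in cfg.lof_backgrounds)
    loe_by_key = {(e.gene, e.subject): e for e in cfg.loe_events}
    imprint_events = {ev.gene: ev for ev in cfg.imprinting_events}

    phased = rng.random(n_total) < cfg.trio_fraction
    # subjects affected by each imprinting event, drawn once per gene
    imprint_affected = {
        g: set(np.flatnonzero(rng.random(n_total) < ev.penetrance))
        for g, ev in imprint_events.items()
    }

    # background SNPs are never LOF: nonsense variants appear only through
    # nmd_events / lof_backgrounds so the NMD denominator is configured, not
    # an accident of sampling
    effect_classes = np.array(["synonymous", "missense", "UTR_3", "UTR_5"])
    effect_probs = np.array([0.46, 0.33, 0.14, 0.07])

    snp_rows: list[dict] = []
    count_rows: list[dict] = []
    truth_ase, truth_imp, truth_nmd = [], [], []

    for si, subject in enumerate(subjects):
        for g in range(cfg.n_genes):
            het = rng.random(n_sites) < het_p
            ase_ev = ase_by_key.get((g, si))
            nmd_ev = nmd_by_key.get((g, si))
            imp_ev = imprint_events.get(g)
            needs_het = ase_ev or nmd_ev or (g, si) in lof_bg or imp_ev
            if needs_het and not het.any():
                het[rng.integers(n_sites)] = True
            idx = np.flatnonzero(het)
            if idx.size == 0:
                continue
            alt_on_hap1 = rng.random(idx.size) < 0.5
            effects = rng.choice(effect_classes, size=idx.size, p=effect_probs)
            lof_site = None
            if nmd_ev is not None or (g, si) in lof_bg:
                lof_site = int(rng.integers(idx.size))
                effects[lof_site] = "nonsense"

            # which haplotype is over-expressed, and by how much
            p_hap1 = cfg.null_allele_fraction  # fraction of reads from hap1
            per_snp_null = True                # null SNPs randomise direction
            if ase_ev is not None:
                high_hap1 = bool(rng.random() < 0.5)
                p_hap1 = ase_ev.allele_fraction if high_hap1 else 1.0 - ase_ev.allele_fraction
                per_snp_null = False
                truth_ase.append({
                    "gene_id": gene_ids[g], "subject_id": subject,
                    "allele_fraction": ase_ev.allele_fraction,
                    "high_hap": "hap1" if high_hap1 else "hap2",
                    "expression_fold": ase_ev.expression_fold,
                })
            elif nmd_ev is not None:
                # the LOF allele (ALT of the nonsense SNP) is under-expressed
                lof_on_hap1 = bool(alt_on_hap1[lof_site])
                p_hap1 = nmd_ev.lof_allele_fraction if lof_on_hap1 else 1.0 - nmd_ev.lof_allele_fraction
                per_snp_null = False
                truth_nmd.append({
                    "gene_id": gene_ids[g], "subject_id": subject,
                    "chrom": genes[g].chrom, "pos": int(site_pos[g][idx[lof_site]]),
                    "lof_allele_fraction": nmd_ev.lof_allele_fraction,
                })
            elif imp_ev is not None and si in imprint_affected[g]:
                if phased[si]:
                    expressed_hap1 = imp_ev.expressed_parent == "maternal"  # hap1 == maternal
                else:
                    expressed_hap1 = bool(rng.random() < 0.5)
                p_hap1 = (cfg.imprint_expressed_fraction if expressed_hap1
                          else 1.0 - cfg.imprint_expressed_fraction)
                per_snp_null = False
                truth_imp.append({
                    "gene_id": gene_ids[g], "subject_id": subject,
                    "expressed_parent": imp_ev.expressed_parent,
                })

            for j, site in enumerate(idx):
                origin = "unknown"
                if phased[si]:
                    origin = "maternal" if alt_on_hap1[j] else "paternal"
                snp_rows.append({
                    "subject_id": subject, "chrom": genes[g].chrom,
                    "pos": int(site_pos[g][site]),
                    "ref": site_ref[g][site], "alt": site_alt[g][site],
                    "gene_id": gene_ids[g],
                    "gq": float(rng.integers(55, 100)),
                    "dna_ab": float(np.clip(rng.normal(0.5, 0.05), 0.2, 0.8)),
                    "parental_origin": origin,
                    "effect_class": str(effects[j]),
                    "population_af": float(rng.uniform(0.01, 0.5)),
                    "alt_on_hap1": bool(alt_on_hap1[j]),
                    "in_alt_exon": bool(site_alt_exon[g][site]),
                })
                for tissue in tissues:
                    depth = int(rng.poisson(cfg.read_depth_mean))
                    p1 = 0.5 if per_snp_null else p_hap1
                    if per_snp_null:
                        p1 = cfg.null_allele_fraction
                    p_alt = p1 if alt_on_hap1[j] else 1.0 - p1
                    if cfg.overdispersion_rho > 0 and depth > 0:
                        rho = cfg.overdispersion_rho
                        a = p_alt * (1 - rho) / rho
                        b = (1 - p_alt) * (1 - rho) / rho
                        p_alt = float(rng.beta(max(a, 1e-9), max(b, 1e-9)))
                    alt_reads = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
                    count_rows.append({
                        "subject_id": subject, "tissue": tissue,
                        "chrom": genes[g].chrom, "pos": int(site_pos[g][site]),
                        "ref": site_ref[g][site], "alt": site_alt[g][site],
                        "ref_reads": depth - alt_reads, "alt_reads": alt_reads,
                    })

    snps = pd.DataFrame(snp_rows)
    for f in aio.SNP_FLAGS:
        snps[f"flag_{f}"] = False
    snps.loc[snps["in_alt_exon"], "flag_alt_spliced_exon"] = True
    counts = pd.DataFrame(count_rows, columns=aio.COUNT_COLUMNS)

    # --- expression matrix ------------------------------------------------
    sample_ids, meta_rows = [], []
    for si, subject in enumerate(subjects):
        for tissue in tissues:
            sample_ids.append(f"{subject}.{tissue}")
            meta_rows.append({"subject_id": subject, "tissue": tissue,
                              "total_aligned_reads": cfg.total_reads_per_sample})
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))

    tissue_factor = {
        t: np.exp(rng.normal(0.0, cfg.expr_tissue_sigma, size=cfg.n_genes)) for t in tissues
    }
    sigma_noise = np.sqrt(np.log1p(cfg.expr_noise_cv**2))
    expr_fold = np.ones((n_total, cfg.n_genes))
    truth_loe = []
    for (g, si), ev in loe_by_key.items():
        expr_fold[si, g] = ev.fold
        truth_loe.append({"gene_id": gene_ids[g], "subject_id": subjects[si], "fold": ev.fold})
    for (g, si), ev in ase_by_key.items():
        expr_fold[si, g] *= ev.expression_fold

    count_mat = np.zeros((cfg.n_genes, len(sample_ids)), dtype=int)
    col = 0
    for si, subject in enumerate(subjects):
        for tissue in tissues:
            noise = np.exp(rng.normal(-0.5 * sigma_noise**2, sigma_noise, size=cfg.n_genes))
            rpm = base_means * tissue_factor[tissue] * noise * expr_fold[si]
            lam = rpm * cfg.total_reads_per_sample / 1e6
            count_mat[:, col] = rng.poisson(lam)
            col += 1
    expr = ExpressionTable(
        counts=pd.DataFrame(count_mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        samples=samples,
    )

    catalog = pd.DataFrame(
        [{"gene_id": gene_ids[ev.gene], "expressed_parent": ev.expressed_parent}
         for ev in cfg.imprinting_events],
        columns=["gene_id", "expressed_parent"],
    )
    truth = {
        "ase": pd.DataFrame(truth_ase, columns=[
            "gene_id", "subject_id", "allele_fraction", "high_hap", "expression_fold"]),
        "imprinting": pd.DataFrame(truth_imp, columns=["gene_id", "subject_id", "expressed_parent"]),
        "nmd": pd.DataFrame(truth_nmd, columns=["gene_id", "subject_id", "chrom", "pos", "lof_allele_fraction"]),
        "loe": pd.DataFrame(truth_loe, columns=["gene_id", "subject_id", "fold"]),
        "contaminated": pd.DataFrame(columns=["subject_id", "chrom", "pos", "higher_base", "flagged"]),
    }
    cohort = SyntheticCohort(
        config=cfg, snps=snps, allele_counts=counts, expression=expr,
        gene_models=genes, fetal_reference=fetal, imprint_catalog=catalog,
        truth=truth, cohort_of=cohort_of,
    )
    if cfg.mapping_bias_fraction > 0:
        cohort = inject_mapping_bias(cohort, cfg.mapping_bias_fraction)
    return cohort


# ---------------------------------------------------------------------------
# contamination and subsampling
# ---------------------------------------------------------------------------

def inject_mapping_bias(
    cohort: SyntheticCohort,
    fraction: float,
    bias_toward_ref: float = 1.0,
    flag_probability: float = 1.0,
    seed: int | None = None,
) -> SyntheticCohort:
    """Give a fraction of genotyped SNPs artifactual monoallelic expression.

    Selected (subject, site) genotype records get all reads on one base —
    the REF base with probability ``bias_toward_ref`` — in every tissue,
    emulating mapping bias from paralogues and repeats. Each contaminated
    SNP receives one positional QC flag (clustered / near an indel / repeat
    region) with probability ``flag_probability`` so the filter cascade can
    find it; near-indel contaminants also add an entry to the cohort's
    indel list. Records belonging to a configured event (gene, subject) are
    never contaminated, keeping truth labels unambiguous. Returns a new
    cohort; the input is not modified.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0,1], got {fraction!r}")
    if not (0.0 <= bias_toward_ref <= 1.0):
        raise ValueError(f"bias_toward_ref must be in [0,1], got {bias_toward_ref!r}")
    out = cohort.copy()
    if fraction == 0.0 or out.snps.empty:
        return out
    cfg = cohort.config
    rng = np.random.default_rng([(int(cfg.seed) if seed is None else int(seed)) % 2**31, 23])

    subjects = _subject_ids(cfg)
    subj_index = {s: i for i, s in enumerate(subjects)}
    gene_index = {g.gene_id: i for i, g in enumerate(cohort.gene_models)}
    event_keys = set()
    for evs in (cfg.ase_events, cfg.nmd_events, cfg.loe_events):
        event_keys.update((e.gene, e.subject) for e in evs)
    event_keys.update((int(g), int(s)) for g, s in cfg.lof_backgrounds)
    imprinted_genes = {e.gene for e in cfg.imprinting_events}

    snps = out.snps
    gidx = snps["gene_id"].map(gene_index)
    sidx = snps["subject_id"].map(subj_index)
    eligible = (
        ~pd.Series(list(zip(gidx, sidx)), index=snps.index).isin(event_keys)
        & ~gidx.isin(imprinted_genes)
    ).to_numpy()
    pick = eligible & (rng.random(len(snps)) < fraction)
    picked = snps.index[pick]
    n_picked = len(picked)
    if n_picked == 0:
        return out

    to_ref = rng.random(n_picked) < bias_toward_ref
    flagged = rng.random(n_picked) < flag_probability
    flag_choices = np.array(["clustered", "near_indel", "repeat_region"])
    flag = rng.choice(flag_choices, size=n_picked)
    for name in flag_choices:
        hit = picked[flagged & (flag == name)]
        snps.loc[hit, f"flag_{name}"] = True

    contam = snps.loc[picked, ["subject_id", "chrom", "pos"]].copy()
    contam["higher_base"] = np.where(to_ref, "ref", "alt")
    contam["flagged"] = flagged
    out.truth["contaminated"] = contam.reset_index(drop=True)

    indel = contam.loc[flagged & (flag == "near_indel"), ["subject_id", "chrom", "pos"]].copy()
    if len(indel):
        indel["pos"] = indel["pos"] + 10
        out.indels = pd.concat([out.indels, indel], ignore_index=True)

    ac = out.allele_counts.merge(
        contam[["subject_id", "chrom", "pos", "higher_base"]],
        on=["subject_id", "chrom", "pos"], how="left",
    )
    depth = ac["ref_reads"] + ac["alt_reads"]
    ref_mask = (ac["higher_base"] == "ref").to_numpy()
    alt_mask = (ac["higher_base"] == "alt").to_numpy()
    ac.loc[ref_mask, "ref_reads"] = depth[ref_mask]
    ac.loc[ref_mask, "alt_reads"] = 0
    ac.loc[alt_mask, "alt_reads"] = depth[alt_mask]
    ac.loc[alt_mask, "ref_reads"] = 0
    out.allele_counts = ac.drop(columns="higher_base")
    return out


def subsample_snps(genotypes: pd.DataFrame, stride: int) -> pd.DataFrame:
    """Retain every ``stride``-th SNP per subject, in genomic order."""
    if stride < 1:
        raise ValueError(f"stride must be >=1, got {stride}")
    if stride == 1 or genotypes.empty:
        return genotypes.copy()

    def chrom_key(c: pd.Series) -> pd.Series:
        stripped = c.str.removeprefix("chr")
        num = pd.to_numeric(stripped, errors="coerce")
        return num.fillna(10_000)

    df = genotypes.copy()
    df["_ck"] = chrom_key(df["chrom"])
    df = df.sort_values(["subject_id", "_ck", "chrom", "pos"], kind="mergesort")
    keep = df.groupby("subject_id", sort=False).cumcount() % stride == 0
    return df[keep].drop(columns="_ck").reset_index(drop=True)


# ---------------------------------------------------------------------------
# canonical study-scale configuration
# ---------------------------------------------------------------------------

def study_config(seed: int = 0) -> SimulationConfig:
    """The default study-scale cohort with all event classes injected.

    Event strengths mirror the regimes the analysis targets: extreme ASE
    near-monoallelic (allele fraction 0.95), imprinting with high
    penetrance, NMD with the LOF allele at 10% of reads, and 20-fold LOE
    knockdowns placed on upper-quartile baseline genes. Mapping-bias
    contamination (4% of genotype records) is sized so that, before QC,
    the reference base dominates biased SNPs at roughly the 87% share seen
    in uncorrected allele-count data.
    """
    cfg = SimulationConfig(seed=seed)
    means = gene_base_means(cfg.n_genes, seed, cfg.expr_mu_log, cfg.expr_sigma_log)
    noncoding, fetal_low, _ = gene_category_flags(
        cfg.n_genes, seed, cfg.noncoding_fraction, cfg.fetal_low_fraction,
        cfg.alt_exon_fraction)
    # events emulate discoveries, which by definition survive the category
    # filters — so they are never placed on noncoding or fetal-low genes
    usable = ~(noncoding | fetal_low)
    order = [int(i) for i in np.argsort(means) if usable[i]]
    upper = order[-30:]            # genes solidly inside the upper quartile
    mid = order[60:160]            # mid-expression genes
    n_cases, n_ctrl = cfg.n_subjects, cfg.n_controls

    ase, nmd, lof_bg, loe = [], [], [], []
    # 20 extreme ASE events: 14 in cases, 6 in controls, distinct genes.
    # Four case events lose total expression (uncompensated allele loss,
    # fold 0.5) and two gain it (fold 6); control events are all
    # dosage-compensated, so expression change is a case-only signal.
    for k in range(20):
        if k < 14:
            subj = k % n_cases
            fold = 0.5 if k < 4 else (6.0 if k < 6 else 1.0)
        else:
            subj = n_cases + (k - 14) % n_ctrl
            fold = 1.0
        ase.append(AseEvent(gene=mid[k], subject=subj, allele_fraction=0.95,
                            expression_fold=fold))
    # imprinting: 3 paternally and 1 maternally expressed genes
    imprint = (
        ImprintingEvent(gene=mid[30], expressed_parent="paternal", penetrance=0.95),
        ImprintingEvent(gene=mid[31], expressed_parent="paternal", penetrance=0.95),
        ImprintingEvent(gene=mid[32], expressed_parent="paternal", penetrance=0.9),
        ImprintingEvent(gene=mid[33], expressed_parent="maternal", penetrance=0.95),
    )
    # NMD: 4 decayed LOF genes and 18 expressed LOF genes in cases
    for k in range(4):
        nmd.append(NmdEvent(gene=mid[40 + k], subject=k % n_cases, lof_allele_fraction=0.1))
    for k in range(18):
        lof_bg.append((mid[44 + k], k % n_cases))
    # LOE: 5 case knockdowns on upper-quartile genes; fold 0.05 is the
    # severe biallelic-loss regime such events show in practice
    for k in range(5):
        loe.append(LoeEvent(gene=upper[5 * k + 2], subject=k % n_cases, fold=0.05))
    return dataclasses.replace(
        cfg, ase_events=tuple(ase), imprinting_events=imprint,
        nmd_events=tuple(nmd), lof_backgrounds=tuple(lof_bg), loe_events=tuple(loe),
    )


def f1_validation_config(seed: int = 0) -> SimulationConfig:
    """An F1-hybrid-style cohort for validating the phasing heuristic.

    Every subject is fully phased and every gene's true expression state is
    known: 20 genes carry strong, callable ASE (allele fraction 0.93, two
    subjects each) and 22 genes carry weak allelic imbalance (fractions
    0.62-0.70, every subject) — genuinely unbalanced but below the extreme
    regime, the raw material for false higher-allele assignments. Read
    depth (mean 15 per SNP, ~2 SNPs per gene) is deliberately modest: the
    heuristic only errs when per-SNP maxima straddle haplotypes.
    """
    n_sub = 10
    events = []
    for g in range(20):
        for s in (g % n_sub, (g + 3) % n_sub):
            events.append(AseEvent(gene=g, subject=s, allele_fraction=0.93))
    for g in range(20, 42):
        for s in range(n_sub):
            events.append(AseEvent(gene=g, subject=s, allele_fraction=0.62 + 0.02 * (g % 5)))
    return SimulationConfig(
        n_subjects=n_sub, n_controls=2, tissues_per_subject=1, n_genes=46,
        snps_per_gene_mean=2.0, read_depth_mean=15.0, trio_fraction=1.0,
        seed=seed, ase_events=tuple(events),
    )


def strong_events_config(seed: int = 0, allele_fraction: float = 0.95) -> SimulationConfig:
    """Fully phased cohort with only strong ASE events (gene depth >> 50).

    Used to show that phased and unphased calling agree exactly when the
    signal is unambiguous.
    """
    n_sub = 8
    events = tuple(
        AseEvent(gene=g, subject=g % n_sub, allele_fraction=allele_fraction)
        for g in range(20)
    )
    return SimulationConfig(
        n_subjects=n_sub, n_controls=2, tissues_per_subject=1, n_genes=60,
        snps_per_gene_mean=3.0, read_depth_mean=60.0, trio_fraction=1.0,
        seed=seed, ase_events=events,
    )


def null_config(
    seed: int = 0,
    n_genes: int = 50,
    n_subjects: int = 6,
    n_controls: int = 6,
    read_depth_mean: float = 60.0,
) -> SimulationConfig:
    """A cohort with no injected events, for calibration checks."""
    return SimulationConfig(
        n_subjects=n_subjects, n_controls=n_controls, tissues_per_subject=1,
        n_genes=n_genes, read_depth_mean=read_depth_mean, seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort directory: per-subject VCFs plus the standard TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    seed, chash = cfg.seed, aio.config_hash(cfg.to_dict())

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for subject, sub in cohort.snps.groupby("subject_id", sort=False):
        aio.write_het_vcf(aio.frame_to_snps(sub), vcf_dir / f"{subject}.vcf", seed=seed)
    aio.write_tsv(cohort.snps[["subject_id", "chrom", "pos", "alt_on_hap1"]],
                  out / "phase_truth.tsv", seed=seed, cfg_hash=chash)
    aio.write_allele_counts(cohort.allele_counts, out / "allele_counts.tsv", seed=seed, cfg_hash=chash)
    aio.write_expression(cohort.expression, out / "expression_counts.tsv", out / "samples.tsv",
                         seed=seed, cfg_hash=chash)
    aio.write_gene_models(cohort.gene_models, out / "gene_models.tsv", seed=seed)
    aio.write_fetal_reference(cohort.fetal_reference, out / "fetal_reference.tsv", seed=seed)
    aio.write_imprint_catalog(cohort.imprint_catalog, out / "imprint_catalog.tsv", seed=seed)
    aio.write_tsv(cohort.indels, out / "indels.tsv", seed=seed, cfg_hash=chash)
    cohorts = pd.DataFrame(sorted(cohort.cohort_of.items()), columns=["subject_id", "cohort"])
    aio.write_tsv(cohorts, out / "cohorts.tsv", seed=seed, cfg_hash=chash)
    for name, df in cohort.truth.items():
        aio.write_tsv(df, out / f"truth_{name}.tsv", seed=seed, cfg_hash=chash)


def load_cohort(in_dir) -> SyntheticCohort:
    """Reconstruct a cohort from a directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        cfg = SimulationConfig.from_dict(yaml.safe_load(fh))
    snp_frames = []
    for vcf_path in sorted((src / "vcf").glob("*.vcf")):
        snp_frames.append(aio.snps_to_frame(aio.read_het_vcf(vcf_path)))
    snps = pd.concat(snp_frames, ignore_index=True)
    phase = aio.read_tsv(src / "phase_truth.tsv")
    snps = snps.merge(phase, on=["subject_id", "chrom", "pos"], how="left")
    snps["alt_on_hap1"] = snps["alt_on_hap1"].fillna(False).astype(bool)
    snps["in_alt_exon"] = snps["flag_alt_spliced_exon"]
    truth = {}
    for path in sorted(src.glob("truth_*.tsv")):
        truth[path.stem.removeprefix("truth_")] = aio.read_tsv(path)
    cohorts = aio.read_tsv(src / "cohorts.tsv")
    return SyntheticCohort(
        config=cfg,
        snps=snps,
        allele_counts=aio.read_allele_counts(src / "allele_counts.tsv"),
        expression=aio.read_expression(src / "expression_counts.tsv", src / "samples.tsv"),
        gene_models=aio.read_gene_models(src / "gene_models.tsv"),
        fetal_reference=aio.read_fetal_reference(src / "fetal_reference.tsv"),
        imprint_catalog=aio.read_imprint_catalog(src / "imprint_catalog.tsv"),
        truth=truth,
        indels=aio.read_tsv(src / "indels.tsv"),
        cohort_of=dict(zip(cohorts["subject_id"], cohorts["cohort"])),
    )
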