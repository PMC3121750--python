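"""Synthetic case-control cohorts under a polygenic liability model.

The generator emulates the structure of a GWAS case-control dataset:
biallelic SNPs in Hardy-Weinberg equilibrium with a configurable MAF
spectrum, a polygenic liability (standardized genetic score plus normal
residual, threshold set by the prevalence ``K``), case-control
ascertainment at any case:control ratio, nuisance covariates (sex, age,
a latent ancestry component, two genotyping platforms with differential
missingness), optional case misclassification, optional related pairs,
and twin-pair affection statuses under the same liability model.

Genotypes are stored as int8 minor-allele dosages with ``MISSING = -1``;
liability construction uses genotypes standardized as
``(x - 2p) / sqrt(2p(1-p))``, matching the standardization used for
genetic-relationship matrices downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from scipy.stats import norm

from .liability import liability_params
from .twins import TwinCounts

__all__ = [
    "MISSING",
    "ArchitectureSpec",
    "Cohort",
    "simulate_cohort",
    "inject_platform_artifacts",
    "misclassify_cases",
    "inject_related_pairs",
    "simulate_twin_counts",
    "write_cohort",
    "load_cohort",
    "write_vcf",
    "read_vcf",
]

MISSING: int = -1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of a simulated trait.

    ``maf_dist`` is ``("uniform", lo, hi)`` or ``("point", p)``;
    ``effect_dist`` currently ``"normal"`` (per-causal-SNP standardized
    effects drawn N(0,1) then rescaled so their squared sum is exactly
    ``h2_l``).  ``covariate_effects`` maps covariate names (``sex``,
    ``age``, ``ancestry``) to liability loadings; their variance counts
    against the unit liability budget.
    """

    m: int = 1000
    m_causal: int = 100
    h2_l: float = 0.3
    K: float = 0.01
    maf_dist: tuple = ("uniform", 0.05, 0.5)
    effect_dist: str = "normal"
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m_causal > self.m:
            raise ValueError("m_causal cannot exceed m")
        if self.h2_l > 0 and self.m_causal == 0:
            raise ValueError("h2_l > 0 requires at least one causal SNP")
        if not 0.0 <= self.h2_l <= 1.0:
            raise ValueError(f"h2_l must be in [0, 1], got {self.h2_l}")
        unknown = set(self.covariate_effects) - {"sex", "ancestry"}
        if unknown:
            raise ValueError(f"unsupported covariate_effects keys: {sorted(unknown)}")
        var_cov = sum(v * v for v in self.covariate_effects.values())
        if self.h2_l + var_cov > 1.0:
            raise ValueError(
                f"infeasible variance budget: h2_l={self.h2_l} plus covariate "
                f"variance {var_cov:.3f} exceeds 1"
            )


@dataclass
class Cohort:
    """A case-control sample: phenotypes/covariates, dosages, SNP metadata.

    ``samples``: DataFrame with columns sample_id, status (0/1), sex (0/1),
    age, platform ({v1, v2}), ancestry (latent score; observed proxy for
    principal components before MDS is run).
    ``genotypes``: (n, m) int8 minor-allele dosage, ``MISSING`` for no-call.
    ``snps``: DataFrame with snp_id, chrom, pos (1-based), allele_major,
    allele_minor, maf (generating frequency), true_beta (liability per
    minor-allele copy; 0 for non-causal).
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    snps: pd.DataFrame
    spec: ArchitectureSpec | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def status(self) -> np.ndarray:
        return self.samples["status"].to_numpy()

    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with NaN for missing calls."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        return g

    def copy(self) -> "Cohort":
        return Cohort(
            samples=self.samples.copy(),
            genotypes=self.genotypes.copy(),
            snps=self.snps.copy(),
            spec=self.spec,
        )


_BASES = np.array(list("ACGT"))


def _draw_mafs(spec: ArchitectureSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.maf_dist[0]
    if kind == "uniform":
        _, lo, hi = spec.maf_dist
        return rng.uniform(lo, hi, size=spec.m)
    if kind == "point":
        return np.full(spec.m, float(spec.maf_dist[1]))
    raise ValueError(f"unknown maf_dist {spec.maf_dist!r}")


def _make_snp_table(
    spec: ArchitectureSpec, mafs: np.ndarray, beta_dosage: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    m = spec.m
    major_idx = rng.integers(0, 4, size=m)
    minor_idx = (major_idx + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"rs{100000 + i}" for i in range(m)],
            "chrom": (np.arange(m) % 22 + 1).astype(str),
            "pos": (np.arange(m) // 22 + 1) * 50_000 + 10_000,
            "allele_major": _BASES[major_idx],
            "allele_minor": _BASES[minor_idx],
            "maf": mafs,
            "true_beta": beta_dosage,
        }
    )


def simulate_cohort(
    spec: ArchitectureSpec, n_case: int, n_control: int,
    template: "Cohort | None" = None,
) -> Cohort:
    """Simulate an ascertained case-control cohort.

    Population individuals are drawn in batches — HWE genotypes at each
    SNP's MAF, liability = standardized-genotype score + covariate terms +
    N(0, residual) with the residual sized so total liability variance is
    1 — and affected individuals (liability above the prevalence
    threshold) fill the case quota while the rest fill the control quota.
    Deterministic given ``spec.seed``.

    ``template`` reuses an existing cohort's SNP panel (ids, alleles,
    MAFs, true effects), drawing only new individuals — the setup for an
    external-validation cohort from the same population.
    """
    rng = np.random.default_rng(spec.seed)
    p = liability_params(spec.K)
    if template is not None:
        mafs = template.snps["maf"].to_numpy(dtype=float)
        beta_dosage = template.snps["true_beta"].to_numpy(dtype=float)
        sd_dosage = np.sqrt(2.0 * mafs * (1.0 - mafs))
        beta_std = beta_dosage * sd_dosage
        causal = np.flatnonzero(beta_std != 0.0)
        spec = replace(
            spec,
            m=len(mafs),
            m_causal=int(causal.size),
            h2_l=float(np.sum(beta_std**2)),
        )
    else:
        mafs = _draw_mafs(spec, rng)
        beta_std = np.zeros(spec.m)
        causal = rng.choice(spec.m, size=spec.m_causal, replace=False)
        if spec.m_causal > 0 and spec.h2_l > 0:
            raw = rng.standard_normal(spec.m_causal)
            if spec.effect_dist != "normal":
                raise ValueError(f"unknown effect_dist {spec.effect_dist!r}")
            raw *= np.sqrt(spec.h2_l / np.sum(raw**2))
            beta_std[causal] = raw
        sd_dosage = np.sqrt(2.0 * mafs * (1.0 - mafs))
        beta_dosage = beta_std / sd_dosage

    cov_load = dict(spec.covariate_effects)
    var_cov = sum(v * v for v in cov_load.values())
    resid_sd = np.sqrt(max(0.0, 1.0 - spec.h2_l - var_cov))

    # during ascertainment only the causal columns are drawn (liability does
    # not depend on the others); non-causal genotypes are filled in for the
    # retained samples afterwards, which is distributionally identical
    causal_sorted = np.sort(causal)
    noncausal = np.setdiff1d(np.arange(spec.m), causal_sorted)
    need_case, need_control = n_case, n_control
    g_cases, g_ctrls = [], []
    anc_cases, anc_ctrls = [], []
    sex_cases, sex_ctrls = [], []
    max_total = int(1e8)
    drawn = 0
    while need_case > 0 or need_control > 0:
        nb = int(
            min(
                500_000,
                max(
                    2_000,
                    1.5 * need_case / spec.K if need_case > 0 else need_control * 1.2,
                ),
            )
        )
        drawn += nb
        if drawn > max_total:
            raise RuntimeError(
                f"ascertainment exceeded {max_total} population draws; "
                f"check K={spec.K} against requested counts"
            )
        gc = rng.binomial(
            2, mafs[causal_sorted][None, :], size=(nb, causal_sorted.size)
        ).astype(np.int8)
        score = (
            (gc - 2.0 * mafs[causal_sorted]) / sd_dosage[causal_sorted]
        ) @ beta_std[causal_sorted]
        sex = rng.integers(0, 2, size=nb)
        ancestry = rng.standard_normal(nb)
        liab = score + resid_sd * rng.standard_normal(nb)
        if "sex" in cov_load:
            liab += cov_load["sex"] * (sex - 0.5) * 2.0
        if "ancestry" in cov_load:
            liab += cov_load["ancestry"] * ancestry
        case = liab > p.t
        take_case = min(need_case, int(case.sum()))
        take_ctrl = min(need_control, int((~case).sum()))
        if take_case:
            idx = np.flatnonzero(case)[:take_case]
            g_cases.append(gc[idx])
            anc_cases.append(ancestry[idx])
            sex_cases.append(sex[idx])
            need_case -= take_case
        if take_ctrl:
            idx = np.flatnonzero(~case)[:take_ctrl]
            g_ctrls.append(gc[idx])
            anc_ctrls.append(ancestry[idx])
            sex_ctrls.append(sex[idx])
            need_control -= take_ctrl

    n_total = n_case + n_control
    genotypes = np.empty((n_total, spec.m), dtype=np.int8)
    genotypes[:, causal_sorted] = np.vstack(g_cases + g_ctrls)
    if noncausal.size:
        genotypes[:, noncausal] = rng.binomial(
            2, mafs[noncausal][None, :], size=(n_total, noncausal.size)
        ).astype(np.int8)
    ancestry = np.concatenate(anc_cases + anc_ctrls)
    sex = np.concatenate(sex_cases + sex_ctrls)
    status = np.concatenate([np.ones(n_case, int), np.zeros(n_control, int)])
    # ages loosely mimic a late-onset disease study: cases older than controls
    age = np.where(
        status == 1,
        rng.normal(62.0, 9.0, size=n_case + n_control),
        rng.normal(48.0, 13.0, size=n_case + n_control),
    ).clip(18, 95)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n_case + n_control)],
            "status": status,
            "sex": sex,
            "age": np.round(age, 1),
            "platform": "v1",
            "ancestry": ancestry,
        }
    )
    snps = (
        template.snps.copy()
        if template is not None
        else _make_snp_table(spec, mafs, beta_dosage, rng)
    )
    return Cohort(samples=samples, genotypes=genotypes, snps=snps, spec=spec)


def inject_platform_artifacts(
    c: Cohort,
    frac_platform2: float = 0.3,
    missing_by_platform: tuple[float, float] = (0.01, 0.05),
    error_rate: float = 0.0,
    seed: int | None = None,
) -> Cohort:
    """Assign platforms and apply differential missingness / genotype error.

    A ``frac_platform2`` fraction of samples is relabeled ``v2``; each
    platform gets its own per-call missing rate, and genotype errors move
    a call to one of the other two dosage values symmetrically.
    """
    for r in (frac_platform2, *missing_by_platform, error_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rates must be in [0, 1], got {r}")
    out = c.copy()
    rng = np.random.default_rng(seed)
    n, m = out.genotypes.shape
    plat2 = rng.uniform(size=n) < frac_platform2
    out.samples["platform"] = np.where(plat2, "v2", "v1")
    if error_rate > 0:
        err = rng.uniform(size=(n, m)) < error_rate
        shift = rng.integers(1, 3, size=(n, m)).astype(np.int8)
        g = out.genotypes
        ok = g != MISSING
        out.genotypes = np.where(err & ok, (g + shift) % 3, g).astype(np.int8)
    miss_rate = np.where(plat2, missing_by_platform[1], missing_by_platform[0])
    miss = rng.uniform(size=(n, m)) < miss_rate[:, None]
    out.genotypes = np.where(miss, MISSING, out.genotypes).astype(np.int8)
    return out


def misclassify_cases(c: Cohort, rate: float, seed: int | None = None) -> Cohort:
    """Replace a fraction of cases with unaffected phenocopies.

    ``rate`` of the case slots are refilled by individuals drawn from the
    control pool and relabeled as cases (mimicking false-positive case
    ascertainment, e.g. self-report error); the displaced true cases are
    dropped, so the case count is preserved and the control count shrinks.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if rate == 0.0:
        return c.copy()
    rng = np.random.default_rng(seed)
    status = c.status
    cases = np.flatnonzero(status == 1)
    ctrls = np.flatnonzero(status == 0)
    k = int(round(rate * cases.size))
    if k > ctrls.size:
        raise ValueError(
            f"need {k} controls to phenocopy but only {ctrls.size} available"
        )
    drop_cases = rng.choice(cases, size=k, replace=False)
    promote = rng.choice(ctrls, size=k, replace=False)
    out = c.copy()
    out.samples.loc[out.samples.index[promote], "status"] = 1
    keep = np.setdiff1d(np.arange(c.n_samples), drop_cases)
    out.samples = out.samples.iloc[keep].reset_index(drop=True)
    out.genotypes = out.genotypes[keep]
    return out


def inject_related_pairs(
    c: Cohort, n_pairs: int, a: float = 0.5, seed: int | None = None
) -> Cohort:
    """Overwrite samples to create related pairs with expected GRM entry ``a``.

    Pair ``i`` consists of sample ``i`` and sample ``n-1-i``; the latter's
    genotype is resampled SNP-by-SNP as a copy of the former with
    probability ``a`` and a fresh HWE draw otherwise, which gives genotype
    correlation (hence expected genomic relationship) ``a``.  Injected
    pair ids are recorded in ``samples['related_pair']``.
    """
    if n_pairs > c.n_samples // 2:
        raise ValueError("n_pairs exceeds n/2")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"relationship must be in [0, 1], got {a}")
    rng = np.random.default_rng(seed)
    out = c.copy()
    mafs = c.snps["maf"].to_numpy()
    n = c.n_samples
    pair_col = np.full(n, -1, int)
    for i in range(n_pairs):
        src, dst = i, n - 1 - i
        copy_mask = rng.uniform(size=c.n_snps) < a
        fresh = rng.binomial(2, mafs).astype(np.int8)
        out.genotypes[dst] = np.where(copy_mask, c.genotypes[src], fresh)
        pair_col[src] = pair_col[dst] = i
    out.samples["related_pair"] = pair_col
    return out


def simulate_twin_counts(
    h2: float,
    K: float,
    n_pairs_mz: int,
    n_pairs_dz: int,
    p_double_ascertain: float = 0.5,
    seed: int | None = None,
) -> tuple[TwinCounts, TwinCounts]:
    """Simulate ascertained twin concordance counts under the liability model.

    Pair liabilities are bivariate normal with correlation ``h2`` (MZ) or
    ``h2 / 2`` (DZ); pairs with at least one affected member are
    ascertained, concordant pairs are split into doubly/singly
    ascertained by an independent Bernoulli(``p_double_ascertain``).
    ``n_pairs_*`` counts ascertained pairs (pairs with no affected member
    never enter a twin series).
    """
    rng = np.random.default_rng(seed)
    t = liability_params(K).t
    out = []
    for zyg, r in (("MZ", h2), ("DZ", h2 / 2.0)):
        n_conc = n_single = n_disc = 0
        need = n_pairs_mz if zyg == "MZ" else n_pairs_dz
        got = 0
        while got < need:
            nb = max(10_000, int(1.5 * (need - got) / (2 * K)))
            z1 = rng.standard_normal(nb)
            z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(nb)
            a1, a2 = z1 > t, z2 > t
            asc = a1 | a2
            both = (a1 & a2)[asc]
            take = min(need - got, int(asc.sum()))
            both = both[:take]
            got += take
            nb_conc = int(both.sum())
            dbl = rng.uniform(size=nb_conc) < p_double_ascertain
            n_conc += int(dbl.sum())
            n_single += nb_conc - int(dbl.sum())
            n_disc += take - nb_conc
        out.append(TwinCounts(zyg, n_conc, n_single, n_disc))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# serialization


def write_cohort(c: Cohort, out_dir: str | Path, vcf: bool = False) -> dict[str, Path]:
    """Write a cohort as TSVs (dosage, samples, SNP metadata, truth) + VCF.

    The dosage table follows the PLINK ``--recode A`` dialect: one row per
    sample (id, status, sex, age, platform, then per-SNP 0/1/2 minor-allele
    counts with NA for missing).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    dosage = pd.DataFrame(
        c.genotypes, columns=c.snps["snp_id"], index=c.samples.index
    ).astype(object)
    dosage[c.genotypes == MISSING] = pd.NA
    dosage = pd.concat(
        [c.samples[["sample_id", "status", "sex", "age", "platform"]], dosage],
        axis=1,
    )
    paths["dosage"] = out_dir / "dosage.tsv"
    dosage.to_csv(paths["dosage"], sep="\t", index=False, na_rep="NA")

    paths["samples"] = out_dir / "samples.tsv"
    c.samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["snps"] = out_dir / "snps.tsv"
    c.snps.drop(columns=["true_beta"]).to_csv(paths["snps"], sep="\t", index=False)
    paths["truth"] = out_dir / "truth.tsv"
    c.snps[["snp_id", "allele_minor", "true_beta"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    if vcf:
        paths["vcf"] = out_dir / "genotypes.vcf"
        write_vcf(c, paths["vcf"])
    return paths


def load_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (TSV layout)."""
    in_dir = Path(in_dir)
    samples = pd.read_csv(in_dir / "samples.tsv", sep="\t")
    snps = pd.read_csv(in_dir / "snps.tsv", sep="\t")
    truth_path = in_dir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        snps = snps.merge(truth[["snp_id", "true_beta"]], on="snp_id", how="left")
    else:
        snps["true_beta"] = 0.0
    dosage = pd.read_csv(in_dir / "dosage.tsv", sep="\t")
    g = dosage[snps["snp_id"]].to_numpy(dtype=float)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8)
    return Cohort(samples=samples, genotypes=g, snps=snps)


def write_vcf(c: Cohort, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF v4.2 with GT records."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(c.snps["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in c.samples["sample_id"]:
        header.add_sample(str(sid))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        snps = c.snps.sort_values(["chrom", "pos"], kind="stable")
        for j in snps.index:
            row = c.snps.loc[j]
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["allele_major"]), str(row["allele_minor"])),
                id=str(row["snp_id"]),
            )
            col = c.genotypes[:, c.snps.index.get_loc(j)]
            for i, sid in enumerate(c.samples["sample_id"]):
                d = int(col[i])
                if d == MISSING:
                    rec.samples[str(sid)]["GT"] = (None, None)
                else:
                    rec.samples[str(sid)]["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
            vf.write(rec)


def read_vcf(path: str | Path, samples: pd.DataFrame | None = None) -> Cohort:
    """Read a GT-only VCF into a :class:`Cohort`.

    ``samples`` optionally supplies phenotypes/covariates by ``sample_id``;
    otherwise status is set to -1 (unknown).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        rows, geno_cols = [], []
        for rec in vf:
            rows.append(
                {
                    "snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": str(rec.chrom),
                    "pos": rec.pos,
                    "allele_major": rec.ref,
                    "allele_minor": rec.alts[0] if rec.alts else ".",
                }
            )
            col = np.empty(len(sample_ids), dtype=np.int8)
            for i, sid in enumerate(sample_ids):
                gt = rec.samples[sid]["GT"]
                col[i] = MISSING if gt is None or None in gt else int(sum(gt))
            geno_cols.append(col)
    snps = pd.DataFrame(rows)
    g = np.column_stack(geno_cols) if geno_cols else np.empty((len(sample_ids), 0), np.int8)
    gf = g.astype(float)
    gf[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        snps["maf"] = np.nanmean(gf, axis=0) / 2.0
    snps["true_beta"] = 0.0
    if samples is None:
        samples = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": -1,
                "sex": 0,
                "age": np.nan,
                "platform": "v1",
                "ancestry": 0.0,
            }
        )
    else:
        samples = (
            pd.DataFrame({"sample_id": sample_ids})
            .merge(samples, on="sample_id", how="left")
        )
    return Cohort(samples=samples, genotypes=g, snps=snps)
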