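"""Synthetic data with known ground truth for every pipeline stage.

The transcriptome generator emulates a two-condition (stem-cell-depleted
SCd vs stem-cell-enriched SCe), three-replicate paired RiboSeq/RNA-seq
experiment: per-gene expression is log-normal, counts are negative
binomial with a gene-shared dispersion, footprint profiles are generated
at per-nucleotide resolution (so the start-to-body statistic is a genuine
positional quantity), and spiked effects — RNA abundance, translation
efficiency, start-window (s2b) redistribution and 5'UTR (uORF) occupancy
— are recorded in a truth table.  An s2b spike redistributes ribosome
density within the CDS without changing total CDS occupancy, so a pure
initiation-pausing change is visible to s2b but not to RO, mirroring the
phenotype class the statistic exists to detect.

The screen generator draws T0 counts multinomially at a configured
coverage (default 600-fold over the library) and depletes guides of
essential genes at the end point, with nontargeting guides following the
null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationRecord, write_annotation_tsv
from .io_tables import SampleRecord, SampleSheet, write_gmt, write_tsv
from .quantify import PositionalProfile

DEFAULT_LEN_PROBS = {
    19: 0.01, 20: 0.01, 21: 0.02, 22: 0.02, 23: 0.03, 24: 0.04, 25: 0.06,
    26: 0.08, 27: 0.12, 28: 0.18, 29: 0.18, 30: 0.12, 31: 0.08, 32: 0.05,
}


@dataclass
class SimParams:
    """Generator settings; defaults are the emulated study conditions.

    ``log_mean_expression``/``sigma_expression`` set the natural-log
    normal over per-sample expected CDS footprint counts (median ~300,
    a deeply sequenced footprint library); ``dispersion`` is the shared NB
    dispersion (0.02, tight biological replicates of an organoid line);
    ``base_start_enrichment`` is the initiation-proximal density excess
    present in every gene.  Effect fractions partition disjoint spiked
    gene classes; shifts are multiplicative with random sign (a shift s
    becomes s or 1/s).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    conditions: tuple[str, str] = ("SCd", "SCe")
    effect_condition: str = "SCe"
    log_mean_expression: float = math.log(300.0)
    sigma_expression: float = 1.0
    dispersion: float = 0.02
    base_start_enrichment: float = 1.5
    uorf_fraction: float = 0.08
    utr3_fraction: float = 0.01
    rna_scale: float = 1.0
    frac_te: float = 0.05
    te_lfc: float = 1.0
    frac_s2b: float = 0.025
    s2b_shift: float = 4.0
    frac_uorf: float = 0.025
    uorf_shift: float = 4.0
    frac_rna: float = 0.05
    rna_lfc: float = 1.0
    frac_short_cds: float = 0.02
    psite_offset: int = 12
    footprint_min_len: int = 19
    footprint_max_len: int = 32
    lib_size_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes < 10: differential stages need a null "
                             "background")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        fracs = (self.frac_te, self.frac_s2b, self.frac_uorf, self.frac_rna)
        if any(not (0 <= f <= 1) for f in fracs) or sum(fracs) > 1:
            raise ValueError("effect fractions must lie in [0,1] and sum <= 1")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        if self.effect_condition not in self.conditions:
            raise ValueError("effect_condition must be one of conditions")


@dataclass
class SimulatedTranscriptome:
    params: SimParams
    records: dict[str, AnnotationRecord]
    models: dict[str, AnnotationRecord]          # gene_id -> primary record
    profiles: dict[str, dict[str, PositionalProfile]]  # sample -> tid -> profile
    rna_counts: pd.DataFrame                     # genes x RNA samples
    sheet: SampleSheet
    truth: pd.DataFrame
    expression: pd.Series = field(repr=False, default=None)

    def occupancy(self, **kwargs) -> pd.DataFrame:
        """Stacked per-gene occupancy metrics over all footprint samples."""
        from .quantify import quantify_samples
        return quantify_samples(self.profiles, self.models, **kwargs)

    def rpf_conditions(self) -> list[str]:
        sub = self.sheet.subset(assay="RPF")
        return [s.condition for s in sub]

    def rna_conditions(self) -> list[str]:
        sub = self.sheet.subset(assay="RNA")
        return [s.condition for s in sub]


def _nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial draws with mean ``mean`` and dispersion ``alpha``."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 0.0))
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def _scatter_uniform(rng: np.random.Generator, arr: np.ndarray,
                     lo: int, hi: int, count: int) -> None:
    """Place ``count`` footprints uniformly over positions [lo, hi)."""
    if count <= 0 or hi <= lo:
        return
    arr[lo:hi] += rng.multinomial(count, np.full(hi - lo, 1.0 / (hi - lo)))


def simulate_transcriptome(params: SimParams) -> SimulatedTranscriptome:
    """Generate annotation, footprint profiles, RNA counts and ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    tids = [f"t{i:05d}" for i in range(n)]

    # transcript structure; a small fraction of short CDSs (< 100 nt)
    # exercises the s2b exclusion path downstream
    utr5 = rng.integers(60, 301, size=n)
    short = rng.random(n) < params.frac_short_cds
    cds = np.where(short, 3 * rng.integers(10, 33, size=n),
                   3 * rng.integers(67, 1001, size=n))
    utr3 = rng.integers(50, 401, size=n)
    records = {tids[i]: AnnotationRecord(tids[i], genes[i], int(utr5[i]),
                                         int(cds[i]), int(utr3[i]), True)
               for i in range(n)}
    models = {genes[i]: records[tids[i]] for i in range(n)}

    expr = rng.lognormal(params.log_mean_expression, params.sigma_expression,
                         size=n)

    # disjoint spiked classes with random effect signs
    order = rng.permutation(n)
    n_te = round(params.frac_te * n)
    n_s2b = round(params.frac_s2b * n)
    n_uorf = round(params.frac_uorf * n)
    n_rna = round(params.frac_rna * n)
    idx_te = order[:n_te]
    idx_s2b = order[n_te:n_te + n_s2b]
    idx_uorf = order[n_te + n_s2b:n_te + n_s2b + n_uorf]
    idx_rna = order[n_te + n_s2b + n_uorf:n_te + n_s2b + n_uorf + n_rna]

    te_lfc = np.zeros(n)
    te_lfc[idx_te] = params.te_lfc * rng.choice([-1.0, 1.0], size=n_te)
    s2b_shift = np.ones(n)
    s2b_shift[idx_s2b] = params.s2b_shift ** rng.choice([-1.0, 1.0], size=n_s2b)
    uorf_shift = np.ones(n)
    uorf_shift[idx_uorf] = params.uorf_shift ** rng.choice([-1.0, 1.0], size=n_uorf)
    rna_lfc = np.zeros(n)
    rna_lfc[idx_rna] = params.rna_lfc * rng.choice([-1.0, 1.0], size=n_rna)

    truth = pd.DataFrame({
        "gene_id": genes,
        "true_logFC_RNA": rna_lfc,
        "true_logFC_TE": te_lfc,
        "true_s2b_shift": s2b_shift,
        "true_uORF_shift": uorf_shift,
        "is_dropout_essential": False,
        "effect_condition": params.effect_condition,
    })

    samples = []
    for assay in ("RNA", "RPF"):
        for cond in params.conditions:
            for rep in range(1, params.n_replicates + 1):
                samples.append(SampleRecord(f"{cond}_{assay}_r{rep}", cond,
                                            assay, rep))
    sheet = SampleSheet(samples)

    tx_len = utr5 + cds + utr3
    offset = params.psite_offset
    window = np.minimum(90, cds)
    enrich = params.base_start_enrichment
    alpha = params.dispersion
    eff = params.effect_condition

    rna_cols: dict[str, np.ndarray] = {}
    profiles: dict[str, dict[str, PositionalProfile]] = {}
    for s in sheet:
        f = rng.uniform(*params.lib_size_range)
        is_eff = s.condition == eff
        rfac = np.exp2(rna_lfc) if is_eff else 1.0
        if s.assay == "RNA":
            mean = params.rna_scale * expr * (tx_len / 1000.0) * rfac * f
            rna_cols[s.sample_id] = _nb(rng, mean, alpha)
            continue
        tfac = np.exp2(te_lfc) if is_eff else 1.0
        sfac = s2b_shift if is_eff else np.ones(n)
        ufac = uorf_shift if is_eff else 1.0
        M = expr * rfac * tfac * f
        ws = window * enrich * sfac
        wb = (cds - window).astype(float)
        start_mean = M * ws / (ws + wb)
        body_mean = M * wb / (ws + wb)
        utr5_mean = params.uorf_fraction * expr * rfac * ufac * f
        utr3_mean = params.utr3_fraction * M
        # replicate overdispersion is a property of the transcript's output
        # in that library, so one gamma multiplier is shared by all regions
        # of a gene within a sample (Poisson-gamma: each region's marginal
        # is NB with the configured dispersion, while positional ratios
        # such as s2b cancel the shared biological noise)
        gam = rng.gamma(1.0 / alpha, alpha, size=n)
        k_start = rng.poisson(gam * start_mean)
        k_body = rng.poisson(gam * body_mean)
        k_utr5 = rng.poisson(gam * utr5_mean)
        k_utr3 = rng.poisson(gam * utr3_mean)

        sample_profiles: dict[str, PositionalProfile] = {}
        # P-sites are only placed where an in-bounds 19-32 nt read can
        # represent them: offsets [psite_offset, tx_len - (min_len - offset))
        tail = params.footprint_min_len - offset
        for i in range(n):
            arr = np.zeros(tx_len[i], dtype=np.int64)
            a = int(utr5[i])
            b = a + int(cds[i])
            w = int(window[i])
            _scatter_uniform(rng, arr, offset, a, int(k_utr5[i]))
            _scatter_uniform(rng, arr, a, a + w, int(k_start[i]))
            _scatter_uniform(rng, arr, a + w, b, int(k_body[i]))
            _scatter_uniform(rng, arr, b, int(tx_len[i]) - tail, int(k_utr3[i]))
            sample_profiles[tids[i]] = PositionalProfile(tids[i], arr)
        profiles[s.sample_id] = sample_profiles

    rna_counts = pd.DataFrame(rna_cols, index=pd.Index(genes, name="gene_id"))
    return SimulatedTranscriptome(params, records, models, profiles,
                                  rna_counts, sheet, truth,
                                  pd.Series(expr, index=genes))


# ---------------------------------------------------------------------------
# screen simulation

@dataclass
class SimulatedScreen:
    counts: pd.DataFrame          # guides x samples
    sheet: SampleSheet
    truth: pd.DataFrame           # gene_id, is_dropout_essential


def simulate_screen(library: pd.DataFrame, coverage: float = 600.0,
                    moi: float = 0.3, dropout_effect: float = 3.0,
                    n_essential: int = 20,
                    essential_genes: list[str] | None = None,
                    n_replicates: int = 3, seed: int = 0,
                    guide_lfc_sd: float = 0.5,
                    null_lfc_sd: float = 0.15) -> SimulatedScreen:
    """Simulate T0 and end-point screen counts over a guide library.

    T0 counts are multinomial at ``coverage x library size`` expected
    depth (library representation log-normal across guides); end-point
    counts depress guides of essential genes by ``dropout_effect`` log2
    units (guide-level heterogeneity ``guide_lfc_sd``), while all other
    guides — nontargeting included — follow a tight null.  ``moi`` is
    recorded metadata (infection happens upstream of counting).
    """
    if library.empty:
        raise ValueError("library is empty")
    if coverage < 50:
        raise ValueError("coverage < 50 gives unusable count depth")
    if dropout_effect <= 0:
        raise ValueError("dropout effect must be > 0 (this is a dropout screen)")
    rng = np.random.default_rng(seed)
    guides = library["guide_id"].to_numpy()
    gene_of = library["gene_id"].to_numpy()
    n_guides = guides.size

    target_genes = sorted(set(gene_of[library["class"].to_numpy() == "targeting"])
                          if "class" in library.columns
                          else set(g for g in gene_of if g != "NONTARGETING"))
    if essential_genes is None:
        if n_essential > len(target_genes):
            raise ValueError("n_essential exceeds the number of targeting genes")
        essential_genes = sorted(rng.choice(target_genes, size=n_essential,
                                            replace=False))
    ess = np.isin(gene_of, essential_genes)
    if "class" in library.columns:
        ess |= library["class"].to_numpy() == "POSCTRL"

    w0 = rng.lognormal(0.0, 0.25, size=n_guides)
    lfc = np.where(ess, rng.normal(-dropout_effect, guide_lfc_sd, size=n_guides),
                   rng.normal(0.0, null_lfc_sd, size=n_guides))
    w_end = w0 * np.exp2(lfc)

    cols: dict[str, np.ndarray] = {}
    samples = []
    for rep in range(1, n_replicates + 1):
        depth = int(round(coverage * n_guides * rng.uniform(0.8, 1.2)))
        cols[f"T0_r{rep}"] = rng.multinomial(depth, w0 / w0.sum())
        samples.append(SampleRecord(f"T0_r{rep}", "screen", "SCREEN_T0", rep))
    for rep in range(1, n_replicates + 1):
        depth = int(round(coverage * n_guides * rng.uniform(0.8, 1.2)))
        cols[f"END_r{rep}"] = rng.multinomial(depth, w_end / w_end.sum())
        samples.append(SampleRecord(f"END_r{rep}", "screen", "SCREEN_END", rep))

    counts = pd.DataFrame(cols, index=pd.Index(guides, name="guide_id"))
    truth_genes = sorted(set(gene_of) - {"NONTARGETING"})
    truth = pd.DataFrame({
        "gene_id": truth_genes,
        "is_dropout_essential": [g in set(essential_genes) for g in truth_genes],
    })
    return SimulatedScreen(counts, SampleSheet(samples), truth)


# ---------------------------------------------------------------------------
# fixture writing

def _write_gtf(records: dict[str, AnnotationRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gtf fixture\n")
        for rec in records.values():
            attrs = (f'gene_id "{rec.gene_id}"; transcript_id '
                     f'"{rec.transcript_id}"; tag "appris_principal"')
            fh.write(f"{rec.transcript_id}\tsim\texon\t1\t{rec.tx_len}\t.\t+\t.\t"
                     f"{attrs}\n")
            if rec.cds_len > 0:
                fh.write(f"{rec.transcript_id}\tsim\tCDS\t{rec.utr5_len + 1}\t"
                         f"{rec.utr5_len + rec.cds_len}\t.\t+\t.\t{attrs}\n")


def _profile_to_alignments(profile: PositionalProfile, offset: int,
                           len_probs: dict[int, float],
                           rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Collapse a P-site profile into (five_prime_pos, length, count) rows."""
    lens = np.array(sorted(len_probs))
    probs = np.array([len_probs[k] for k in lens], dtype=float)
    probs /= probs.sum()
    rows = []
    tx_len = profile.counts.size
    for pos in np.flatnonzero(profile.counts):
        c = int(profile.counts[pos])
        five = int(pos) - offset
        ok = lens <= tx_len - five
        p = probs[ok] / probs[ok].sum()
        draws = rng.multinomial(c, p)
        for length, k in zip(lens[ok], draws):
            if k > 0:
                rows.append((five, int(length), int(k)))
    return rows


def write_fixtures(sim: SimulatedTranscriptome, directory: str | Path,
                   screen: SimulatedScreen | None = None,
                   library: pd.DataFrame | None = None,
                   annotation_format: str = "gtf",
                   n_random_sets: int = 3, random_set_size: int = 30) -> dict[str, Path]:
    """Write files exactly consumable by the package's readers.

    Emits annotation (GTF or TSV), sample sheet, RNA counts, per-sample
    footprint alignment tables, gene sets (an "OXPHOS-like" set built from
    the positively TE-spiked genes, a "glycolysis-like" set from the
    negative ones, plus seeded random sets), the truth table and, when
    given, screen counts and the guide library.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.params.seed + 1)
    meta = {"seed": sim.params.seed}
    out: dict[str, Path] = {}

    if annotation_format == "gtf":
        out["annotation"] = directory / "annotation.gtf"
        _write_gtf(sim.records, out["annotation"])
    else:
        out["annotation"] = directory / "annotation.tsv"
        write_annotation_tsv(sim.records, out["annotation"])

    out["sample_sheet"] = directory / "sample_sheet.tsv"
    sim.sheet.write(out["sample_sheet"], **meta)

    out["rna_counts"] = directory / "rna_counts.tsv"
    write_tsv(sim.rna_counts.reset_index(), out["rna_counts"], **meta)

    len_probs = {k: v for k, v in DEFAULT_LEN_PROBS.items()
                 if sim.params.footprint_min_len <= k <= sim.params.footprint_max_len}
    for sample_id, profs in sim.profiles.items():
        rows = []
        for tid in sorted(profs):
            for five, length, count in _profile_to_alignments(
                    profs[tid], sim.params.psite_offset, len_probs, rng):
                rows.append({"transcript_id": tid, "five_prime_pos": five,
                             "length": length, "count": count})
        path = directory / f"alignments_{sample_id}.tsv"
        write_tsv(pd.DataFrame(rows), path, sample=sample_id, **meta)
        out[f"alignments_{sample_id}"] = path

    te_up = sim.truth.loc[sim.truth["true_logFC_TE"] > 0, "gene_id"].tolist()
    te_dn = sim.truth.loc[sim.truth["true_logFC_TE"] < 0, "gene_id"].tolist()
    sets: dict[str, list[str]] = {}
    if te_up:
        sets["OXPHOS_LIKE"] = te_up
    if te_dn:
        sets["GLYCOLYSIS_LIKE"] = te_dn
    genes = sim.truth["gene_id"].to_numpy()
    for k in range(n_random_sets):
        sets[f"RANDOM_{k + 1}"] = sorted(rng.choice(
            genes, size=min(random_set_size, genes.size), replace=False))
    out["gene_sets"] = directory / "gene_sets.gmt"
    write_gmt(sets, out["gene_sets"])

    out["truth"] = directory / "truth.tsv"
    write_tsv(sim.truth, out["truth"], **meta)

    if library is not None:
        out["library"] = directory / "library.tsv"
        write_tsv(library, out["library"], **meta)
    if screen is not None:
        out["screen_counts"] = directory / "screen_counts.tsv"
        write_tsv(screen.counts.reset_index(), out["screen_counts"], **meta)
        out["screen_sheet"] = directory / "screen_sample_sheet.tsv"
        screen.sheet.write(out["screen_sheet"], **meta)
        out["screen_truth"] = directory / "screen_truth.tsv"
        write_tsv(screen.truth, out["screen_truth"], **meta)
    return out


def make_guide_pools(models: dict[str, AnnotationRecord], seed: int = 0,
                     n_per_pool: int = 6) -> pd.DataFrame:
    """Pre-ranked synthetic guide pools for every (gene, region).

    Stands in for the external Brie/GeCKO (CDS) and designed (UTR5/UP)
    guide sources; sequences are seeded random 20-mers free of Esp3I sites.
    """
    from .screen_design import REGIONS, random_protospacers
    rng = np.random.default_rng(seed)
    genes = sorted(models)
    rows = []
    seqs = random_protospacers(len(genes) * len(REGIONS) * n_per_pool, rng)
    it = iter(seqs)
    for gene in genes:
        for region in REGIONS:
            source = "BRIE" if region == "CDS" else "DESIGNED"
            for _ in range(n_per_pool):
                rows.append({"gene_id": gene, "region": region,
                             "protospacer": next(it), "source": source})
    return pd.DataFrame(rows, columns=["gene_id", "region", "protospacer",
                                       "source"])
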