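"""Rule-based CRISPR dropout-library design from differential tables.

Selection rules (union, deduplicated, with per-rule provenance):

1. significant TE change (adj P < 0.1) OR s2b change (raw P < 0.1)
   -> target the CDS;
2. significant RO change (adj P < 0.05) with no significant RNA change
   (adj P > 0.05) -> target the CDS;
3. significant uORF RO change (adj P < 0.05) -> target three regions:
   CDS, the uORF (UTR5) and the region upstream of the uORF (UP).

Five guides per (gene, region) are taken from pre-ranked pools, plus
nontargeting and positive-control guides; oligos for Golden Gate cloning
carry Esp3I (CGTCTC) adapter flanks, so any guide containing an internal
Esp3I site is rejected before selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("riboscreen.screen_design")

ESP3I_SITE = "CGTCTC"
ESP3I_SITE_RC = "GAGACG"
REGIONS = ("CDS", "UTR5", "UP")
NONTARGETING = "NONTARGETING"
POSCTRL = "POSCTRL"

RULE_TE_S2B = "TE_OR_S2B"
RULE_RO_NOT_RNA = "RO_NOT_RNA"
RULE_UORF = "UORF"


def has_esp3i_site(seq: str) -> bool:
    s = seq.upper()
    return ESP3I_SITE in s or ESP3I_SITE_RC in s


def _sig_mask(table: pd.DataFrame, col: str, thresh: float,
              below: bool = True) -> pd.Series:
    """Per-gene boolean mask; untested genes are False (the rule abstains)."""
    t = table.set_index("gene_id")
    vals = t[col].where(t["tested"])
    return (vals < thresh) if below else (vals > thresh)


def select_candidates(te: pd.DataFrame, s2b: pd.DataFrame, ro: pd.DataFrame,
                      rna: pd.DataFrame, uorf: pd.DataFrame,
                      te_adjp_max: float = 0.1, s2b_p_max: float = 0.1,
                      ro_adjp_max: float = 0.05, rna_adjp_min: float = 0.05,
                      uorf_adjp_max: float = 0.05,
                      s2b_use_adjusted_p: bool = False) -> pd.DataFrame:
    """Apply the three selection rules to the five differential tables.

    Returns one row per (gene_id, region) with a ``rules`` column listing
    the rules that selected it (comma-joined), sorted for determinism.
    A gene untested in a table makes that rule abstain for the gene.
    """
    r1_te = _sig_mask(te, "adjP", te_adjp_max)
    r1_s2b = _sig_mask(s2b, "adjP" if s2b_use_adjusted_p else "p", s2b_p_max)
    r2_ro = _sig_mask(ro, "adjP", ro_adjp_max)
    r2_rna = _sig_mask(rna, "adjP", rna_adjp_min, below=False)
    r3 = _sig_mask(uorf, "adjP", uorf_adjp_max)

    selected: dict[tuple[str, str], set[str]] = {}

    def add(genes, region, rule):
        for g in genes:
            selected.setdefault((g, region), set()).add(rule)

    rule1 = set(r1_te[r1_te.fillna(False)].index) | set(r1_s2b[r1_s2b.fillna(False)].index)
    add(rule1, "CDS", RULE_TE_S2B)
    combined = r2_ro.reindex(r2_ro.index).fillna(False) & \
        r2_rna.reindex(r2_ro.index).fillna(False)
    add(set(combined[combined].index), "CDS", RULE_RO_NOT_RNA)
    rule3 = set(r3[r3.fillna(False)].index)
    for region in REGIONS:
        add(rule3, region, RULE_UORF)

    rows = [{"gene_id": g, "region": r, "rules": ",".join(sorted(rules))}
            for (g, r), rules in selected.items()]
    out = pd.DataFrame(rows, columns=["gene_id", "region", "rules"])
    out = out.sort_values(["gene_id", "region"], ignore_index=True)
    log.info("select_candidates: %d (gene, region) targets over %d genes "
             "(rule1=%d genes, rule2=%d, rule3=%d)",
             len(out), out["gene_id"].nunique() if len(out) else 0,
             len(rule1), int(combined.sum()), len(rule3))
    return out


@dataclass
class LibraryManifest:
    """Bookkeeping of library composition by guide class."""

    n_targeting: int
    n_nontargeting: int
    n_positive_control: int
    by_region: dict[str, int]
    deficits: dict[tuple[str, str], int]

    @property
    def total(self) -> int:
        return self.n_targeting + self.n_nontargeting + self.n_positive_control

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": "targeting", "count": self.n_targeting},
                {"class": "nontargeting", "count": self.n_nontargeting},
                {"class": "positive_control", "count": self.n_positive_control}]
        for region, n in sorted(self.by_region.items()):
            rows.append({"class": f"targeting_{region}", "count": n})
        rows.append({"class": "total", "count": self.total})
        return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def random_protospacers(n: int, rng: np.random.Generator,
                        forbidden_substrings_of: list[str] | None = None
                        ) -> list[str]:
    """Seeded random 20-mers, free of Esp3I sites and (optionally) of exact
    matches inside the supplied sequences."""
    out: list[str] = []
    haystack = "|".join(forbidden_substrings_of or [])
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=20))
        if has_esp3i_site(seq):
            continue
        if haystack and seq in haystack:
            continue
        out.append(seq)
    return out


def _guide_valid(proto: str, flank5: str | None, flank3: str | None) -> bool:
    """No Esp3I site inside the protospacer, nor created at an adapter
    junction (5 nt of flank context on each side covers any 6-mer site)."""
    if has_esp3i_site(proto):
        return False
    if flank5 is not None and has_esp3i_site(flank5[-5:] + proto[:5]):
        return False
    if flank3 is not None and has_esp3i_site(proto[-5:] + flank3[:5]):
        return False
    return True


def build_library(targets: pd.DataFrame, pools: pd.DataFrame,
                  n_nontargeting: int = 100,
                  positive_control_genes: list[str] | None = None,
                  n_per_region: int = 5, seed: int = 0,
                  transcript_sequences: list[str] | None = None,
                  flank5: str | None = None, flank3: str | None = None
                  ) -> tuple[pd.DataFrame, LibraryManifest]:
    """Assemble the guide library.

    ``pools`` has columns gene_id, region, protospacer, source, in the
    pool's own priority order; the first ``n_per_region`` valid guides per
    target are taken (guides with internal Esp3I sites are rejected before
    selection, duplicates across genes flagged).  Nontargeting guides are
    generated with the fixed seed and screened against
    ``transcript_sequences`` for exact matches.  Positive-control genes
    take CDS-pool guides under the POSCTRL class.
    """
    rng = np.random.default_rng(seed)
    pools = pools.copy()
    valid = pools["protospacer"].map(lambda p: _guide_valid(p, flank5, flank3))
    n_rej = int((~valid).sum())
    if n_rej:
        log.info("build_library: rejected %d pool guides with internal or "
                 "junction Esp3I sites", n_rej)
    pools = pools[valid]
    pool_map: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for row in pools.itertuples(index=False):
        pool_map.setdefault((row.gene_id, row.region), []).append(
            (row.protospacer, row.source))

    records = []
    deficits: dict[tuple[str, str], int] = {}
    by_region: dict[str, int] = {}

    def take(gene, region, klass):
        avail = pool_map.get((gene, region), [])
        chosen = avail[:n_per_region]
        if len(chosen) < n_per_region:
            deficits[(gene, region)] = n_per_region - len(chosen)
            log.info("build_library: pool deficit %d for (%s, %s)",
                     n_per_region - len(chosen), gene, region)
        for i, (proto, source) in enumerate(chosen, start=1):
            records.append({"guide_id": f"{gene}_{region}_g{i}",
                            "gene_id": gene, "region": region,
                            "protospacer": proto, "source": source,
                            "class": klass})
        return len(chosen)

    targets = targets.sort_values(["gene_id", "region"])
    for row in targets.itertuples(index=False):
        n = take(row.gene_id, row.region, "targeting")
        by_region[row.region] = by_region.get(row.region, 0) + n
    n_targeting = len(records)

    n_pos = 0
    for gene in sorted(positive_control_genes or []):
        n_pos += take(gene, "CDS", POSCTRL)

    nt_seqs = [s for s in random_protospacers(
        2 * n_nontargeting, rng, transcript_sequences)
        if _guide_valid(s, flank5, flank3)][:n_nontargeting]
    for i, seq in enumerate(nt_seqs, start=1):
        records.append({"guide_id": f"NT_g{i:04d}", "gene_id": NONTARGETING,
                        "region": "NONE", "protospacer": seq,
                        "source": "CONTROL", "class": "nontargeting"})

    library = pd.DataFrame(records, columns=["guide_id", "gene_id", "region",
                                             "protospacer", "source", "class"])
    dup = library["protospacer"].duplicated(keep=False)
    if dup.any():
        log.warning("build_library: %d duplicate protospacers across guides",
                    int(dup.sum()))
    library["duplicate_protospacer"] = dup
    manifest = LibraryManifest(n_targeting, len(nt_seqs), n_pos, by_region,
                               deficits)
    log.info("build_library: total %d guides (%d targeting, %d nontargeting, "
             "%d positive control)", manifest.total, n_targeting,
             len(nt_seqs), n_pos)
    return library, manifest


# ---------------------------------------------------------------------------
# oligo assembly and in-silico Esp3I digestion

def esp3i_cut_positions(seq: str) -> list[int]:
    """Top-strand cut positions for all Esp3I sites (CGTCTC(1/5)).

    A forward site starting at p cuts the top strand at p+7; a
    reverse-complement site (GAGACG) starting at q cuts at q-5.  Positions
    outside the sequence are clipped out (the enzyme cannot cut past the
    molecule's end).
    """
    s = seq.upper()
    cuts = []
    start = 0
    while (p := s.find(ESP3I_SITE, start)) != -1:
        cuts.append(p + 7)
        start = p + 1
    start = 0
    while (q := s.find(ESP3I_SITE_RC, start)) != -1:
        cuts.append(q - 5)
        start = q + 1
    return sorted(c for c in cuts if 0 < c < len(s))


def digest(seq: str) -> list[str]:
    """Fragments of the top strand after Esp3I digestion."""
    cuts = esp3i_cut_positions(seq)
    frags = []
    prev = 0
    for c in cuts:
        frags.append(seq[prev:c])
        prev = c
    frags.append(seq[prev:])
    return frags


class AssemblyError(ValueError):
    pass


def assemble_oligos(library: pd.DataFrame, flank5: str, flank3: str
                    ) -> list[tuple[str, str]]:
    """Build synthesis oligos flank5 + protospacer + flank3 and verify that
    simulated Esp3I digestion releases exactly one protospacer-bearing
    insert fragment.

    Raises :class:`AssemblyError` if a flank lacks an Esp3I site, or if a
    guide's oligo digests into more than the expected fragments (an
    internal site that selection should have filtered; error INTERNAL_SITE).
    """
    if ESP3I_SITE not in flank5.upper():
        raise AssemblyError("5' flank lacks a forward Esp3I site (CGTCTC)")
    if ESP3I_SITE_RC not in flank3.upper():
        raise AssemblyError("3' flank lacks a reverse Esp3I site (GAGACG)")
    oligos = []
    for row in library.itertuples(index=False):
        proto = row.protospacer
        oligo = flank5 + proto + flank3
        n_sites = (oligo.upper().count(ESP3I_SITE)
                   + oligo.upper().count(ESP3I_SITE_RC))
        if n_sites != 2:
            raise AssemblyError(
                f"INTERNAL_SITE: guide {row.guide_id} oligo has {n_sites} Esp3I "
                "sites (expected 2); guide should have been filtered")
        frags = digest(oligo)
        inserts = [f for f in frags if proto in f]
        if len(frags) != 3 or len(inserts) != 1:
            raise AssemblyError(
                f"guide {row.guide_id}: digestion yielded {len(frags)} fragments, "
                f"{len(inserts)} containing the protospacer (expected 3 / 1)")
        oligos.append((row.guide_id, oligo))
    return oligos
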