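"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately use nothing from the gliprio cascade implementation:
plain nested loops over row dicts, and naive linear scans over windows.
"""

from __future__ import annotations


def brute_force_pairs(selected_rows, dme_rows, flank=500_000):
    """Nested-loop variant-CpG pairing on the trait-OR-exposure context rule."""
    pairs = []
    for v in selected_rows:
        for c in dme_rows:
            if not c["significant"]:
                continue
            if c["chrom"] != v["chrom"]:
                continue
            if abs(int(c["pos"]) - int(v["pos"])) > flank:
                continue
            if c["context"] not in (v["trait"], v["exposure"]):
                continue
            pairs.append((v, c))
    return pairs


def brute_force_prioritized(selected_rows, dme_rows, eqtl_rows, eqtm_rows, flank=500_000):
    """Triple-nested-loop join; returns {locus_key: (variants, cpgs, tissues)}.

    locus_key = (gene_id, ancestry_group, trait, exposure).
    """
    loci: dict[tuple, tuple[set, set, set]] = {}
    for v, c in brute_force_pairs(selected_rows, dme_rows, flank):
        for q in eqtl_rows:
            if not q["significant"] or q["variant_id"] != v["variant_id"]:
                continue
            for m in eqtm_rows:
                if (
                    not m["significant"]
                    or m["cpg_id"] != c["cpg_id"]
                    or m["gene_id"] != q["gene_id"]
                ):
                    continue
                key = (q["gene_id"], v["ancestry_group"], v["trait"], v["exposure"])
                vs, cs, ts = loci.setdefault(key, (set(), set(), set()))
                vs.add(v["variant_id"])
                cs.add(c["cpg_id"])
                ts.add(q["tissue"])
    return loci


def linear_scan_query(windows, chrom, pos):
    """Naive point-in-window scan; windows are (chrom, start, end, name)."""
    return sorted(
        name
        for (wchrom, start, end, name) in windows
        if wchrom == chrom and start <= pos <= end
    )
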