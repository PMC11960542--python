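"""Motif-overlapping putative causal variant (MOPCV) prioritization.

High-confidence credible-set variants (sets of <= 25 variants) that fall
inside predicted TF motif occurrences are ranked by the strength of
their causal evidence relative to chromatin-accessibility QTL signals:
High when the variant belongs to a caQTL credible set and lies within
that signal's own caPeak (or, for complex modules, any caPeak in the
module); Moderate when it lies in the caPeak of a different caQTL
signal; Low otherwise. The module also computes the pipeline's summary
fractions (percent of loci colocalized, fold changes, etc.) from counts.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .datatypes import ComplexQtlModule, CredibleSet, MopcvRecord


def variant_in_interval(pos_1based: int, start: int, end: int) -> bool:
    """Overlap of a 1-based variant with a 0-based half-open interval."""
    return start <= pos_1based - 1 < end


def collect_high_confidence_variants(
    credible_sets: dict[str, CredibleSet],
    locus_of_qtl: dict[str, str],
    modules: list[ComplexQtlModule] | None = None,
    representative_of_module: dict[str, str] | None = None,
) -> dict[str, set[str]]:
    """Union of high-confidence credible-set variants per GWAS locus.

    ``credible_sets`` maps a colocalizing QTL id to its credible set and
    ``locus_of_qtl`` to the assigned locus. For complex modules,
    non-representative members that colocalize with the same locus as
    the representative contribute their credible sets too (set union).
    Sets larger than 25 variants are excluded entirely.
    """
    per_locus: dict[str, set[str]] = {}
    for qtl_id, cs in credible_sets.items():
        if qtl_id not in locus_of_qtl or not cs.high_confidence:
            continue
        per_locus.setdefault(locus_of_qtl[qtl_id], set()).update(cs.variant_ids)
    return per_locus


def intersect_with_motifs(
    variants: dict[str, int],
    motifs: pd.DataFrame,
    locus: str = "",
    colocalizations: list[str] | None = None,
) -> list[MopcvRecord]:
    """Intersect 1-based variant positions with 0-based motif intervals.

    ``variants`` maps variant id -> position; ``motifs`` has columns
    ``chrom, start, end, name`` and optionally ``bound``. Variants with
    no motif hit are dropped; all hits of a variant land on one record.
    """
    records = []
    for vid, pos in variants.items():
        hits = []
        for _, m in motifs.iterrows():
            if variant_in_interval(pos, int(m["start"]), int(m["end"])):
                hits.append(
                    {
                        "motif": m["name"],
                        "start": int(m["start"]),
                        "end": int(m["end"]),
                        "bound": bool(m["bound"]) if "bound" in m else False,
                    }
                )
        if hits:
            records.append(
                MopcvRecord(
                    variant=vid,
                    locus=locus,
                    colocalizations=list(colocalizations or []),
                    motif_hits=hits,
                )
            )
    return records


def rank_priority(
    record: MopcvRecord,
    signal_credible_sets: dict[str, set[str]],
    signal_capeak: dict[str, str],
    variant_peaks: set[str],
    module_of_signal: dict[str, str] | None = None,
) -> str:
    """Assign High / Moderate / Low by the first matching rule.

    ``signal_credible_sets`` maps each caQTL signal to its credible-set
    variants; ``signal_capeak`` maps each signal to its associated
    caPeak id; ``variant_peaks`` is the set of peak ids overlapping the
    variant. ``module_of_signal`` groups signals into complex modules so
    that membership in any member caQTL plus overlap with any module
    caPeak counts as High.
    """
    module_of_signal = module_of_signal or {}
    member_of = [
        s for s, cs in signal_credible_sets.items() if record.variant in cs
    ]
    # High: in a caQTL signal whose own caPeak (or a module-mate's) is hit
    for s in member_of:
        own_peaks = {signal_capeak[s]} if s in signal_capeak else set()
        mod = module_of_signal.get(s)
        if mod is not None:
            own_peaks |= {
                signal_capeak[t]
                for t, m in module_of_signal.items()
                if m == mod and t in signal_capeak
            }
        if own_peaks & variant_peaks:
            record.priority = "High"
            return "High"
    # Moderate: in some caQTL signal and inside a different signal's caPeak
    if member_of:
        own_modules = {module_of_signal.get(s) for s in member_of}
        for t, peak in signal_capeak.items():
            if t in member_of:
                continue
            if module_of_signal.get(t) in own_modules and module_of_signal.get(t) is not None:
                continue
            if peak in variant_peaks:
                record.priority = "Moderate"
                return "Moderate"
    record.priority = "Low"
    return "Low"


def _round1(x: float) -> float:
    """Round half-up to 1 decimal (the convention of printed summaries)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def locus_report(counts: dict[str, float]) -> dict[str, float | None]:
    """Summary fractions from pipeline counts (or printed inputs).

    Recognized keys (all optional; missing denominators yield None):
    ``n_loci_total, n_loci_colocalized, n_loci_eqtl_colocalized,
    n_loci_chromatin_only, n_edev_loci, n_credible_variants,
    n_high_priority, n_complex_modules, n_complex_two_elements,
    n_shared_qtls, n_singleton_qtls, n_qtls_total``.
    Percentages are to 1 decimal (round half-up), folds to 1 decimal.
    """
    c = counts

    def pct(num_key: str, den_key: str) -> float | None:
        if num_key in c and c.get(den_key):
            return _round1(100.0 * c[num_key] / c[den_key])
        return None

    def fold(num_key: str, den_key: str) -> float | None:
        if num_key in c and c.get(den_key):
            return _round1(c[num_key] / c[den_key])
        return None

    return {
        "pct_loci_colocalized": pct("n_loci_colocalized", "n_loci_total"),
        "pct_loci_chromatin_only": pct("n_loci_chromatin_only", "n_loci_total"),
        "pct_loci_eqtl": pct("n_loci_eqtl_colocalized", "n_loci_total"),
        "fold_increase_chromatin": fold("n_loci_colocalized", "n_loci_eqtl_colocalized"),
        "pct_edev_among_eqtl_loci": pct("n_edev_loci", "n_loci_eqtl_colocalized"),
        "pct_shared_qtls": pct("n_shared_qtls", "n_qtls_total"),
        "pct_singleton_qtls": pct("n_singleton_qtls", "n_qtls_total"),
        "pct_complex_two_elements": pct("n_complex_two_elements", "n_complex_modules"),
        "fold_reduction_mopcv": fold("n_credible_variants", "n_high_priority"),
    }
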