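"""Temporal (early-developmental vs adult) QTL classification.

Each SNP-eGene pair carries a local false sign rate (LFSR) per tissue;
tissues are labeled early-developmental (EDev) or adult. A pair is
EDev-specific when significant (LFSR < alpha) in at least one EDev
tissue and in no adult tissue, adult-specific for the reverse, shared
when significant in both groups, and dropped when significant nowhere.
An LFSR of exactly alpha counts as not significant. Classifications are
mapped onto a cohort's own eQTLs and reconciled across complex-QTL
modules, whose members by construction share one genetic signal.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ComplexQtlModule

CLASSES = ("EDev-specific", "adult-specific", "shared", "dropped")
COHORT_CLASSES = ("EDev-specific", "Shared", "No Association")


def classify_temporal(
    lfsr_row: pd.Series,
    edev_tissues: list[str],
    adult_tissues: list[str],
    alpha: float = 0.05,
) -> str:
    """Classify one LFSR row; missing (NaN) entries mean untested."""
    edev = lfsr_row[list(edev_tissues)].dropna()
    adult = lfsr_row[list(adult_tissues)].dropna()
    if edev.empty and adult.empty:
        raise ValueError("all LFSR entries missing")
    edev_sig = bool((edev < alpha).any())
    adult_sig = bool((adult < alpha).any())
    if edev_sig and adult_sig:
        return "shared"
    if edev_sig:
        return "EDev-specific"
    if adult_sig:
        return "adult-specific"
    return "dropped"


def classify_lfsr_matrix(
    lfsr: pd.DataFrame,
    edev_tissues: list[str],
    adult_tissues: list[str],
    alpha: float = 0.05,
) -> pd.Series:
    """Row-wise classification; rows must be tested in both tissue groups."""
    tested_edev = lfsr[list(edev_tissues)].notna().any(axis=1)
    tested_adult = lfsr[list(adult_tissues)].notna().any(axis=1)
    valid = lfsr.loc[tested_edev & tested_adult]
    return valid.apply(
        classify_temporal, axis=1, args=(edev_tissues, adult_tissues, alpha)
    )


def annotate_cohort_eqtls(
    classes: pd.Series,
    cohort_eqtls: pd.DataFrame,
    lfsr: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Map pair classes onto the cohort's own eQTLs.

    ``cohort_eqtls`` needs columns ``pair`` (SNP-eGene id) and
    ``tissue`` (the discovery tissue, which must also be an LFSR
    column when ``lfsr`` is given). EDev-specific maps to EDev-specific
    and shared to Shared, but only when the pair is significant in its
    own discovery tissue; adult-specific, dropped, inconsistent or
    unmatched pairs become No Association.
    """
    rows = []
    for _, rec in cohort_eqtls.iterrows():
        pair = rec["pair"]
        if pair not in classes.index:
            rows.append((pair, rec["tissue"], "No Association", "unmatched"))
            continue
        cls = classes.loc[pair]
        if cls not in ("EDev-specific", "shared"):
            rows.append((pair, rec["tissue"], "No Association", cls))
            continue
        if lfsr is not None:
            own = lfsr.loc[pair, rec["tissue"]] if rec["tissue"] in lfsr.columns else np.nan
            if not (np.isfinite(own) and own < alpha):
                rows.append((pair, rec["tissue"], "No Association", "inconsistent_with_discovery"))
                continue
        label = "EDev-specific" if cls == "EDev-specific" else "Shared"
        rows.append((pair, rec["tissue"], label, cls))
    return pd.DataFrame(rows, columns=["pair", "tissue", "annotation", "reason"])


def propagate_complex_annotation(
    annotations: dict[str, str],
    modules: list[ComplexQtlModule],
) -> dict[str, str]:
    """Reconcile member annotations within each complex module.

    Rule order: (1) any member No Association makes the whole module
    No Association; (2) otherwise a mix of EDev-specific and Shared
    becomes Shared; (3) otherwise the unanimous class is kept. Applying
    the propagation twice equals applying it once.
    """
    out = dict(annotations)
    for module in modules:
        members = [m.element for m in module.members]
        present = [out[m] for m in members if m in out]
        if not present:
            continue
        if "No Association" in present:
            label = "No Association"
        elif "EDev-specific" in present and "Shared" in present:
            label = "Shared"
        else:
            label = present[0]
        for m in members:
            if m in out:
                out[m] = label
    return out


def effectsize_correlation_by_group(
    betas: pd.DataFrame,
    tissue_pairs: list[tuple[str, str]],
    groups: pd.Series,
    min_pairs: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r^2 of effect sizes per (EDev tissue, adult tissue) per group.

    ``betas``: rows = SNP-eGene pairs, columns = tissues. Returns the
    per-cell r^2 table and two-sided t-tests comparing r^2 distributions
    between each group pair.
    """
    from scipy import stats as sps

    rows = []
    for group in groups.unique():
        members = groups.index[groups == group]
        sub = betas.loc[betas.index.intersection(members)]
        for edev_t, adult_t in tissue_pairs:
            cell = sub[[edev_t, adult_t]].dropna()
            if len(cell) < min_pairs or cell[edev_t].std() == 0 or cell[adult_t].std() == 0:
                r2 = np.nan
            else:
                r = np.corrcoef(cell[edev_t], cell[adult_t])[0, 1]
                r2 = r * r
            rows.append({"group": group, "edev_tissue": edev_t, "adult_tissue": adult_t, "r2": r2})
    table = pd.DataFrame(rows)

    tests = []
    gnames = list(groups.unique())
    for i in range(len(gnames)):
        for j in range(i + 1, len(gnames)):
            a = table.loc[table["group"] == gnames[i], "r2"].dropna()
            b = table.loc[table["group"] == gnames[j], "r2"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                t, p = sps.ttest_ind(a, b)
            else:
                t, p = np.nan, np.nan
            tests.append({"group_a": gnames[i], "group_b": gnames[j], "t": t, "p": p})
    return table, pd.DataFrame(tests)
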