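"""Localization filtering, pathway binning, and overrepresentation tests."""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnnotationRecord, SiteSummary

__all__ = [
    "PATHWAY_BINS",
    "filter_mitochondrial",
    "bin_pathways",
    "overrepresentation",
    "enrichment_report",
]

#: The fixed 12-way pathway vocabulary; anything else maps to "other".
PATHWAY_BINS = (
    "TCA cycle",
    "innate immunity",
    "transport",
    "urea cycle",
    "fatty acid oxidation",
    "redox regulation",
    "Fe-S biogenesis",
    "apoptosis",
    "tRNA-ligases",
    "mt ribosomal subunits",
    "ETC",
    "mt transcription and translation",
)


def _as_annotation_map(
    annotations: Mapping[str, AnnotationRecord] | Iterable[AnnotationRecord],
) -> dict[str, AnnotationRecord]:
    if isinstance(annotations, Mapping):
        return dict(annotations)
    return {a.protein_id: a for a in annotations}


def filter_mitochondrial(
    summaries: Sequence[SiteSummary],
    annotations: Mapping[str, AnnotationRecord] | Iterable[AnnotationRecord],
) -> tuple[list[SiteSummary], dict]:
    """Keep only summaries on mitochondrially annotated proteins.

    Proteins absent from the annotation table count as non-mitochondrial
    (with a warning). Returns the retained subset and a coverage report:
    protein and cysteine counts plus the mitochondrial row fraction.
    """
    ann = _as_annotation_map(annotations)
    if not ann:
        raise ValueError("annotation table is empty")
    missing = sorted({s.site.protein_id for s in summaries} - set(ann))
    if missing:
        warnings.warn(
            f"{len(missing)} protein(s) missing from the annotation table "
            f"treated as non-mitochondrial: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    retained = [
        s
        for s in summaries
        if s.site.protein_id in ann and ann[s.site.protein_id].is_mitochondrial
    ]
    report = {
        "n_input_rows": len(summaries),
        "n_retained_rows": len(retained),
        "n_proteins": len({s.site.protein_id for s in retained}),
        "n_cysteines": len({(s.site.protein_id, s.site.residue) for s in retained}),
        "fraction_mitochondrial": (
            len(retained) / len(summaries) if summaries else 0.0
        ),
    }
    return retained, report


def bin_pathways(
    summaries: Sequence[SiteSummary],
    annotations: Mapping[str, AnnotationRecord] | Iterable[AnnotationRecord],
    high_threshold: float = 5.0,
) -> pd.DataFrame:
    """Assign each protein to its single pathway bin and count sites.

    Returns one row per non-empty bin with the member proteins, the site
    count, and the number of sites whose mean ratio is at least
    ``high_threshold``. Unknown bin labels in the annotation table raise.
    """
    ann = _as_annotation_map(annotations)
    valid = set(PATHWAY_BINS) | {"other"}
    for rec in ann.values():
        if rec.pathway_bin not in valid:
            raise ValueError(f"unknown pathway bin label {rec.pathway_bin!r}")
    proteins: dict[str, set[str]] = defaultdict(set)
    n_sites: dict[str, int] = defaultdict(int)
    n_high: dict[str, int] = defaultdict(int)
    for s in summaries:
        rec = ann.get(s.site.protein_id)
        binned = rec.pathway_bin if rec is not None else "other"
        proteins[binned].add(s.site.protein_id)
        n_sites[binned] += 1
        if s.mean_ratio is not None and s.mean_ratio >= high_threshold:
            n_high[binned] += 1
    rows = []
    for label in list(PATHWAY_BINS) + ["other"]:
        if label not in proteins:
            continue
        rows.append(
            {
                "pathway_bin": label,
                "n_proteins": len(proteins[label]),
                "n_sites": n_sites[label],
                "n_high_sensitivity": n_high[label],
                "proteins": ";".join(sorted(proteins[label])),
            }
        )
    return pd.DataFrame(rows)


def overrepresentation(
    foreground: set[str],
    background: set[str],
    categories: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each category in the foreground.

    p is the upper-tail probability of observing at least the overlap by
    drawing |foreground| proteins from the background without replacement;
    q is the Benjamini–Hochberg adjustment across categories. Fold
    enrichment is (overlap/|fg|) / (|cat ∩ bg|/|bg|).
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    M, N = len(background), len(foreground)
    rows = []
    for name in sorted(categories):
        cat = categories[name] & background
        K = len(cat)
        k = len(cat & foreground)
        expected = N * K / M if M else 0.0
        fold = (k / N) / (K / M) if (N and K) else float("nan")
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else float("nan")
        rows.append(
            {
                "category": name,
                "overlap": k,
                "category_size": K,
                "foreground_size": N,
                "background_size": M,
                "expected_overlap": expected,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        mask = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        if mask.any():
            q[mask.to_numpy()] = stats.false_discovery_control(
                df.loc[mask, "p_value"].to_numpy(), method="bh"
            )
        df["q_value"] = q
    return df


def enrichment_report(
    fractionated: Sequence[SiteSummary],
    reference: Sequence[SiteSummary],
    annotations: Mapping[str, AnnotationRecord] | Iterable[AnnotationRecord],
) -> dict:
    """Mitochondrial-coverage gain of a fractionated run over a reference.

    Reports mitochondrial protein and cysteine counts in each table, the
    fold increases, and the mitochondrial share of rows per table.
    """
    ann = _as_annotation_map(annotations)

    def _counts(summaries: Sequence[SiteSummary]) -> tuple[int, int, float]:
        mito = [
            s
            for s in summaries
            if s.site.protein_id in ann and ann[s.site.protein_id].is_mitochondrial
        ]
        n_prot = len({s.site.protein_id for s in mito})
        n_cys = len({(s.site.protein_id, s.site.residue) for s in mito})
        frac = len(mito) / len(summaries) if summaries else 0.0
        return n_prot, n_cys, frac

    f_prot, f_cys, f_frac = _counts(fractionated)
    r_prot, r_cys, r_frac = _counts(reference)
    if r_prot == 0 or r_cys == 0:
        raise ValueError("reference table has no mitochondrial rows")
    return {
        "fractionated_mito_proteins": f_prot,
        "fractionated_mito_cysteines": f_cys,
        "fractionated_mito_fraction": f_frac,
        "reference_mito_proteins": r_prot,
        "reference_mito_cysteines": r_cys,
        "reference_mito_fraction": r_frac,
        "protein_fold_increase": f_prot / r_prot,
        "cysteine_fold_increase": f_cys / r_cys,
    }
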