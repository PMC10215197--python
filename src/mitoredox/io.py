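"""Readers and writers for the pipeline's text formats.

Every table is TSV with a one-line versioned comment header
(``# mitoredox.tsv.v1 kind=<kind>``) followed by a column header.
Floats are serialized at 6 significant digits. FASTA goes through
Biopython.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationRecord,
    CysteineSite,
    EICTrace,
    OxidationRecord,
    RatioObservation,
    SiteSummary,
    TruthRecord,
)

FORMAT_VERSION = "mitoredox.tsv.v1"
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA → {accession: sequence} (first word of header)."""
    proteome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome[rec.id] = str(rec.seq).upper()
    if not proteome:
        raise ValueError(f"no FASTA records found in {path}")
    return proteome


def write_fasta(proteome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# versioned TSV plumbing


def _write_versioned(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT)
    Path(path).write_text(f"# {FORMAT_VERSION} kind={kind}\n" + buf.getvalue())


def _read_versioned(path: str | Path, kind: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        if FORMAT_VERSION not in header:
            raise ValueError(
                f"{path} does not carry the expected '{FORMAT_VERSION}' header"
            )
        if f"kind={kind}" not in header:
            raise ValueError(f"{path} is not a {kind!r} table ({header})")
        return pd.read_csv(fh, sep="\t")


def _site_columns(site: CysteineSite) -> dict:
    return {
        "protein_id": site.protein_id,
        "residue": site.residue,
        "peptide": site.peptide,
    }


def _site_from_row(row) -> CysteineSite:
    peptide = row["peptide"]
    return CysteineSite(
        protein_id=str(row["protein_id"]),
        residue=int(row["residue"]),
        peptide="" if pd.isna(peptide) else str(peptide),
    )


# ---------------------------------------------------------------------------
# ground truth


def write_truths(truths: Sequence[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            **_site_columns(t.site),
            "fmax_rev": t.fmax_rev,
            "K_mM": t.K,
            "hill": t.hill,
            "firr_frac": t.firr_frac,
            "detect_isotop": t.detect_isotop,
            "detect_oxicat": t.detect_oxicat,
            "basal_ox": t.basal_ox,
            "sensitivity_class": t.sensitivity_class,
        }
        for t in truths
    ]
    _write_versioned(pd.DataFrame(rows), path, "truth")


def read_truths(path: str | Path) -> list[TruthRecord]:
    df = _read_versioned(path, "truth")
    return [
        TruthRecord(
            site=_site_from_row(row),
            fmax_rev=float(row["fmax_rev"]),
            K=float(row["K_mM"]),
            hill=float(row["hill"]),
            firr_frac=float(row["firr_frac"]),
            detect_isotop=float(row["detect_isotop"]),
            detect_oxicat=float(row["detect_oxicat"]),
            basal_ox=float(row["basal_ox"]),
            sensitivity_class=str(row["sensitivity_class"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# per-replicate observations


def write_observations(
    observations: Sequence[RatioObservation], path: str | Path
) -> None:
    rows = [
        {
            **_site_columns(o.site),
            "condition": o.condition,
            "replicate": o.replicate,
            "light_area": o.light_area,
            "heavy_area": o.heavy_area,
            "ratio_LH": o.ratio_LH,
            "capped": int(o.capped),
        }
        for o in observations
    ]
    _write_versioned(pd.DataFrame(rows), path, "observations")


def read_observations(path: str | Path) -> list[RatioObservation]:
    df = _read_versioned(path, "observations")
    return [
        RatioObservation(
            site=_site_from_row(row),
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
            light_area=float(row["light_area"]),
            heavy_area=float(row["heavy_area"]),
            ratio_LH=float(row["ratio_LH"]),
            capped=bool(row["capped"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# summaries


def write_summaries(summaries: Sequence[SiteSummary], path: str | Path) -> None:
    rows = [
        {
            **_site_columns(s.site),
            "condition": s.condition,
            "n_present": s.n_present,
            "mean_ratio": s.mean_ratio,
            "cv": s.cv,
            "sensitivity_class": s.sensitivity_class,
            "implied_oxidation_pct": s.implied_oxidation_pct,
            "flags": ";".join(sorted(s.flags)),
        }
        for s in summaries
    ]
    _write_versioned(pd.DataFrame(rows), path, "summaries")


def read_summaries(path: str | Path) -> list[SiteSummary]:
    df = _read_versioned(path, "summaries")

    def _opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for _, row in df.iterrows():
        flags = row["flags"]
        out.append(
            SiteSummary(
                site=_site_from_row(row),
                condition=str(row["condition"]),
                n_present=int(row["n_present"]),
                mean_ratio=_opt(row["mean_ratio"]),
                cv=_opt(row["cv"]),
                sensitivity_class=(
                    None
                    if pd.isna(row["sensitivity_class"])
                    else str(row["sensitivity_class"])
                ),
                implied_oxidation_pct=_opt(row["implied_oxidation_pct"]),
                flags=frozenset(
                    str(flags).split(";") if isinstance(flags, str) and flags else []
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# oxidation records


def write_oxidation(records: Sequence[OxidationRecord], path: str | Path) -> None:
    rows = [
        {
            **_site_columns(r.site),
            "condition": r.condition,
            "replicate_pcts": ";".join(FLOAT_FORMAT % p for p in r.replicate_pcts),
            "mean_pct": r.mean_pct,
            "sd_pct": r.sd_pct,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    _write_versioned(pd.DataFrame(rows), path, "oxidation")


def read_oxidation(path: str | Path) -> list[OxidationRecord]:
    df = _read_versioned(path, "oxidation")
    out = []
    for _, row in df.iterrows():
        pcts = row["replicate_pcts"]
        flags = row["flags"]
        out.append(
            OxidationRecord(
                site=_site_from_row(row),
                condition=str(row["condition"]),
                replicate_pcts=tuple(
                    float(x)
                    for x in (str(pcts).split(";") if isinstance(pcts, str) and pcts else [])
                ),
                mean_pct=None if pd.isna(row["mean_pct"]) else float(row["mean_pct"]),
                sd_pct=None if pd.isna(row["sd_pct"]) else float(row["sd_pct"]),
                flags=frozenset(
                    str(flags).split(";") if isinstance(flags, str) and flags else []
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotations


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "is_mitochondrial": int(r.is_mitochondrial),
            "pathway_bin": r.pathway_bin,
            "flags": ";".join(sorted(r.known_redox_flags)),
        }
        for r in records
    ]
    _write_versioned(pd.DataFrame(rows), path, "annotations")


def read_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    df = _read_versioned(path, "annotations")
    out = {}
    for _, row in df.iterrows():
        flags = row["flags"]
        out[str(row["protein_id"])] = AnnotationRecord(
            protein_id=str(row["protein_id"]),
            is_mitochondrial=bool(int(row["is_mitochondrial"])),
            pathway_bin=str(row["pathway_bin"]),
            known_redox_flags=frozenset(
                str(flags).split(";") if isinstance(flags, str) and flags else []
            ),
        )
    return out


# ---------------------------------------------------------------------------
# chromatograms (long format)


def write_chromatograms(traces: Sequence[EICTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": tr.site.protein_id,
                    "residue": tr.site.residue,
                    "peptide": tr.site.peptide,
                    "condition": tr.condition,
                    "replicate": tr.replicate,
                    "channel": tr.channel,
                    "time_s": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "protein_id", "residue", "peptide", "condition",
            "replicate", "channel", "time_s", "intensity",
        ]
    )
    _write_versioned(df, path, "chromatograms")


def read_chromatograms(path: str | Path) -> list[EICTrace]:
    df = _read_versioned(path, "chromatograms")
    traces = []
    keys = ["protein_id", "residue", "peptide", "condition", "replicate", "channel"]
    for (pid, residue, peptide, condition, replicate, channel), grp in df.groupby(
        keys, sort=True, dropna=False
    ):
        grp = grp.sort_values("time_s")
        traces.append(
            EICTrace(
                site=CysteineSite(
                    protein_id=str(pid),
                    residue=int(residue),
                    peptide="" if pd.isna(peptide) else str(peptide),
                ),
                channel=str(channel),
                times=grp["time_s"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
                condition=str(condition),
                replicate=int(replicate),
            )
        )
    return traces
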