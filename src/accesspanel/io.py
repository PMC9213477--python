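"""Readers and writers for the plain-text formats used across the pipeline.

All tabular outputs are tab-separated with deterministic column order and
floats rendered with 6 significant digits, so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import PeakSet, empty_frame
from .scoring import CountMatrix, ScoreTrack

FLOAT_FMT = "%.6g"

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signalValue", "pValue", "qValue", "peak"]


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return FLOAT_FMT % x
    return str(x)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_narrowpeak(path, score_column: int = 5, width: int | None = None,
                    label: str = "") -> PeakSet:
    """Read an ENCODE narrowPeak (10-column) file into a PeakSet.

    ``score_column`` selects the score source: 5 (BED score, default) or 8
    (the -log10 p-value column), 1-based as in the format description.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 10:
        raise ValueError(f"{path}: expected 10 narrowPeak columns, got {df.shape[1]}")
    df.columns = NARROWPEAK_COLUMNS[:df.shape[1]]
    score = df.iloc[:, score_column - 1].astype(float)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["name"].astype(str), "score": score,
        "summit_offset": df["peak"].astype(np.int64),
    })
    return PeakSet(out, width=width, label=label)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    df = peaks.df
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["name"],
        "score": [FLOAT_FMT % s for s in df["score"]],
        "strand": ".",
        "signalValue": [FLOAT_FMT % s for s in df["score"]],
        "pValue": -1, "qValue": -1,
        "peak": df["summit_offset"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, width: int | None = None, label: str = "") -> PeakSet:
    """Read BED3/BED6 into a PeakSet (missing name/score filled with defaults)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: need at least 3 BED columns")
    out = pd.DataFrame({"chrom": df[0], "start": df[1], "end": df[2]})
    if ncol >= 4:
        out["name"] = df[3].astype(str)
    if ncol >= 5:
        out["score"] = df[4].astype(float)
    return PeakSet(out, width=width, label=label)


def write_bed6(peaks: PeakSet, path, sidecar: bool = True) -> None:
    """Write BED6 with browser-safe integer scores (0-1000).

    Full-precision scores go to a ``.scores.tsv`` sidecar next to the BED
    when ``sidecar`` is true.
    """
    df = peaks.df
    clamped = np.clip(np.rint(df["score"].to_numpy()), 0, 1000).astype(int)
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                        "end": df["end"], "name": df["name"],
                        "score": clamped, "strand": "."})
    out.to_csv(path, sep="\t", header=False, index=False)
    if sidecar:
        side = pd.DataFrame({"name": df["name"], "score": df["score"]})
        write_tsv(side, str(path) + ".scores.tsv", index=False)


def read_counts(counts_path, samples_path, normalized: str = "raw") -> CountMatrix:
    """Read a region x sample counts TSV plus a sample sheet (sample_id, label)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    if "sample_id" not in sheet or "label" not in sheet:
        raise ValueError(f"{samples_path}: sample sheet needs sample_id and label columns")
    meta = sheet.set_index("sample_id")["label"].astype(str)
    return CountMatrix(counts, meta, normalized)


def write_counts(matrix: CountMatrix, counts_path, samples_path) -> None:
    write_tsv(matrix.counts, counts_path)
    sheet = matrix.sample_meta.rename("label").rename_axis("sample_id").reset_index()
    write_tsv(sheet, samples_path, index=False)


def read_score_track(path) -> ScoreTrack:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("score", "tumor_mean", "blood_weighted_mean"):
        if col not in df:
            raise ValueError(f"{path}: missing column {col!r}")
    ps = float(df["pseudocount"].iloc[0]) if "pseudocount" in df else 0.0
    return ScoreTrack(region_ids=df.index, score=df["score"],
                      tumor_mean=df["tumor_mean"],
                      blood_weighted_mean=df["blood_weighted_mean"],
                      pseudocount=ps)


def write_score_track(track: ScoreTrack, path) -> None:
    df = track.to_frame()
    df["pseudocount"] = track.pseudocount
    write_tsv(df, path)


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                index=False)


def read_variants(path) -> pd.DataFrame:
    """Read variants from a minimal VCF (AF/DP/MMQ/MBQ in INFO) or TSV."""
    if str(path).endswith(".vcf"):
        return _read_minimal_vcf(path)
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "pos", "ref", "alt", "af", "depth", "mmq", "mbq"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    return df


def _read_minimal_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
            rows.append((chrom, int(pos), ref, alt, float(kv.get("AF", "nan")),
                         int(float(kv.get("DP", "0"))), float(kv.get("MMQ", "nan")),
                         float(kv.get("MBQ", "nan"))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af",
                                       "depth", "mmq", "mbq"])


def write_minimal_vcf(variants: pd.DataFrame, path, sample_role: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=MMQ,Number=1,Type=Float,Description="Median mapping quality">\n')
        fh.write('##INFO=<ID=MBQ,Number=1,Type=Float,Description="Median base quality">\n')
        if sample_role:
            fh.write(f"##sample_role={sample_role}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples(index=False):
            info = (f"AF={FLOAT_FMT % r.af};DP={int(r.depth)};"
                    f"MMQ={FLOAT_FMT % r.mmq};MBQ={FLOAT_FMT % r.mbq}")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_json_report(report: dict, path) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=default) + "\n")


def write_manifest(path, subcommand: str, params: dict, inputs: dict) -> None:
    """Machine-readable run manifest: parameters, inputs, seed, version."""
    from . import __version__
    write_json_report({"subcommand": subcommand, "version": __version__,
                       "parameters": params, "inputs": inputs}, path)
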