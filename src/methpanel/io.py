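"""Delimited-table readers and writers for datasets and results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import MethylationDataset

SEP = "\t"
FLOAT_FMT = "%.10g"  # fixed formatting so identical runs are byte-identical


def write_dataset(dataset: MethylationDataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.manifest.to_csv(out / "manifest.tsv", sep=SEP)
    dataset.sample_sheet.to_csv(out / "samples.tsv", sep=SEP, float_format=FLOAT_FMT)
    dataset.beta.to_csv(out / "beta.tsv", sep=SEP, float_format=FLOAT_FMT)
    dataset.detection_p.to_csv(out / "detection_p.tsv", sep=SEP, float_format=FLOAT_FMT)
    dataset.control_intensities.to_csv(out / "controls.tsv", sep=SEP,
                                       float_format=FLOAT_FMT)
    (out / "qc_state.txt").write_text(dataset.qc_state + "\n")


def read_dataset(indir) -> MethylationDataset:
    d = Path(indir)
    manifest = pd.read_csv(d / "manifest.tsv", sep=SEP, index_col=0)
    sheet = pd.read_csv(d / "samples.tsv", sep=SEP, index_col=0)
    for col in ("race_noncaucasian", "origin_noneuropean", "malignancy",
                "syndrome", "low_yield"):
        if col in sheet.columns:
            sheet[col] = sheet[col].map(
                {True: True, False: False, "True": True, "False": False})
    beta = pd.read_csv(d / "beta.tsv", sep=SEP, index_col=0)
    det = pd.read_csv(d / "detection_p.tsv", sep=SEP, index_col=0)
    ctrl = pd.read_csv(d / "controls.tsv", sep=SEP, index_col=0)
    qc_state = "raw"
    if (d / "qc_state.txt").exists():
        qc_state = (d / "qc_state.txt").read_text().strip()
    return MethylationDataset(beta=beta, detection_p=det,
                              control_intensities=ctrl, sample_sheet=sheet,
                              manifest=manifest, qc_state=qc_state)


def write_table(df: pd.DataFrame, path, index=True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=index, float_format=FLOAT_FMT)


def write_qc_report(report, path) -> None:
    rows = [{"id": sid, "kind": "sample", "reason": r}
            for sid, r in report.excluded_samples]
    rows += [{"id": pid, "kind": "probe", "reason": r}
             for pid, r in report.excluded_probes]
    write_table(pd.DataFrame(rows, columns=["id", "kind", "reason"]), path,
                index=False)
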