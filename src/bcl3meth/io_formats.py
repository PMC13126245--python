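"""Readers, writers and validation for on-disk artifacts.

All tabular artifacts are TSV: the beta and intensity matrices have CpGs in
rows and samples in columns, the sample sheet one row per sample, and the
CpG annotation is BED-like with 1-based inclusive coordinates.  Numbers are
serialized with 6 decimal places, which makes repeated writes byte-stable
and round-trips exact at text precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["DatasetBundle", "ValidationError", "load_dataset", "write_dataset"]

FLOAT_FMT = "%.6f"

BETA_FILE = "beta.tsv"
SHEET_FILE = "samples.tsv"
ANNOTATION_FILE = "annotation.tsv"
INTENSITY_FILE = "intensity.tsv"
MANIFEST_FILE = "manifest.json"


class ValidationError(ValueError):
    """Raised when an artifact fails structural or range validation."""


@dataclass
class DatasetBundle:
    """A validated set of cohort artifacts sharing sample and CpG ids."""

    beta: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    intensity: Optional[pd.DataFrame] = None

    def validate(self) -> "DatasetBundle":
        bad = ~((self.beta.values >= 0.0) & (self.beta.values <= 1.0))
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            raise ValidationError(
                f"beta value outside [0,1] at CpG {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {self.beta.iat[i, j]}"
            )
        if self.beta.isna().any().any():
            raise ValidationError("beta matrix contains missing values")
        sheet_ids = set(self.sheet["sample_id"])
        beta_ids = set(self.beta.columns)
        if sheet_ids != beta_ids:
            missing = sorted(sheet_ids ^ beta_ids)
            raise ValidationError(f"sample ids of sheet and beta differ: {missing}")
        ann_ids = set(self.annotation["cpg_id"])
        cpg_ids = set(self.beta.index)
        if ann_ids != cpg_ids:
            missing = sorted(ann_ids ^ cpg_ids)[:20]
            raise ValidationError(f"cpg ids of annotation and beta differ: {missing}")
        parents = self.sheet["followup_of"].fillna("")
        for child, parent in zip(self.sheet["sample_id"], parents):
            if parent and parent not in sheet_ids:
                raise ValidationError(f"followup_of of {child!r} names unknown sample {parent!r}")
        if self.intensity is not None and set(self.intensity.index) != cpg_ids:
            raise ValidationError("intensity probe ids do not match annotation")
        return self


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc


def load_dataset(directory: str | Path) -> DatasetBundle:
    """Load and validate a dataset bundle written by :func:`write_dataset`."""
    d = Path(directory)
    for fname in (BETA_FILE, SHEET_FILE, ANNOTATION_FILE):
        if not (d / fname).exists():
            raise FileNotFoundError(d / fname)
    beta = _read_tsv(d / BETA_FILE, index_col=0)
    beta.index.name = "cpg_id"
    sheet = _read_tsv(d / SHEET_FILE, dtype={"sample_id": str, "followup_of": str})
    sheet["followup_of"] = sheet["followup_of"].fillna("")
    sheet = sheet.set_index("sample_id", drop=False)
    annotation = _read_tsv(d / ANNOTATION_FILE, dtype={"module": str})
    annotation = annotation.set_index("cpg_id", drop=False)
    intensity = None
    if (d / INTENSITY_FILE).exists():
        intensity = _read_tsv(d / INTENSITY_FILE, index_col=0)
        intensity.index.name = "probe_id"
    return DatasetBundle(beta=beta, sheet=sheet, annotation=annotation, intensity=intensity).validate()


def write_dataset(bundle: DatasetBundle, out_dir: str | Path) -> dict:
    """Write a bundle to ``out_dir`` deterministically; return a manifest.

    Sample columns are ordered lexicographically so two writes of the same
    bundle are byte-identical; the manifest lists each file with its row and
    column counts and is also written as ``manifest.json``.
    """
    bundle.validate()
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    cols = sorted(bundle.beta.columns)
    beta = bundle.beta[cols]
    beta.to_csv(d / BETA_FILE, sep="\t", float_format=FLOAT_FMT)
    manifest[BETA_FILE] = {"rows": int(beta.shape[0]), "cols": int(beta.shape[1])}

    sheet = bundle.sheet.reset_index(drop=True).sort_values("sample_id")
    sheet.to_csv(d / SHEET_FILE, sep="\t", index=False, float_format=FLOAT_FMT)
    manifest[SHEET_FILE] = {"rows": int(sheet.shape[0]), "cols": int(sheet.shape[1])}

    ann = bundle.annotation
    ann.to_csv(d / ANNOTATION_FILE, sep="\t", index=False)
    manifest[ANNOTATION_FILE] = {"rows": int(ann.shape[0]), "cols": int(ann.shape[1])}

    if bundle.intensity is not None:
        inten = bundle.intensity[sorted(bundle.intensity.columns)]
        inten.to_csv(d / INTENSITY_FILE, sep="\t", float_format=FLOAT_FMT)
        manifest[INTENSITY_FILE] = {"rows": int(inten.shape[0]), "cols": int(inten.shape[1])}

    with open(d / MANIFEST_FILE, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
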