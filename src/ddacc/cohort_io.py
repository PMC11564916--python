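"""On-disk case layout and run configuration.

A cohort is a directory of patients; each patient directory holds ``ref/``
(reference image, dose, structures) and ``fx_01`` .. ``fx_NN`` fraction
subdirectories (daily image, structures, ground-truth field, arm doses),
all as NIfTI, plus a YAML manifest listing paths and roles.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .grids import (
    read_mask,
    read_vector_field,
    read_volume,
    write_mask,
    write_vector_field,
    write_volume,
)
from .phantom import DoseModelParams, FractionRecord, PatientCase, PhantomParams

__all__ = ["write_case", "load_case", "write_cohort", "load_cohort", "load_params"]

_STRUCT_ORDER = ("CTV", "PTV", "bladder", "rectum", "urethra")


def load_params(config_path: str | Path | None = None, **overrides) -> PhantomParams:
    """PhantomParams from a YAML config file plus keyword overrides."""
    cfg: dict = {}
    if config_path is not None:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("bladder_volume_range", "rectum_volume_range", "drift_mm_per_fraction"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return PhantomParams(**cfg)


def write_case(case: PatientCase, out_dir: str | Path) -> Path:
    """Write one patient case to disk; returns the manifest path."""
    out = Path(out_dir) / case.patient_id
    ref = out / "ref"
    ref.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "patient_id": case.patient_id,
        "params": asdict(case.params),
        "dose_model": asdict(case.dose_model),
        "ref": {"image": "ref/image.nii.gz", "dose": "ref/dose.nii.gz", "structures": {}},
        "fractions": [],
    }
    write_volume(case.ref_image, ref / "image.nii.gz")
    write_volume(case.ref_dose, ref / "dose.nii.gz")
    for lab in _STRUCT_ORDER:
        write_mask(case.ref_structures[lab], ref / f"mask_{lab}.nii.gz")
        manifest["ref"]["structures"][lab] = f"ref/mask_{lab}.nii.gz"
    for fx in case.fractions:
        sub = f"fx_{fx.index:02d}"
        fdir = out / sub
        fdir.mkdir(exist_ok=True)
        entry: dict = {
            "index": fx.index,
            "image": f"{sub}/image.nii.gz",
            "gt_dvf": f"{sub}/gt_dvf.nii.gz",
            "applied_shift": [float(s) for s in fx.applied_shift],
            "structures": {},
        }
        write_volume(fx.image, fdir / "image.nii.gz")
        write_vector_field(fx.gt_dvf_ref_to_fx, fdir / "gt_dvf.nii.gz")
        for lab in _STRUCT_ORDER:
            write_mask(fx.structures[lab], fdir / f"mask_{lab}.nii.gz")
            entry["structures"][lab] = f"{sub}/mask_{lab}.nii.gz"
        if fx.dose_oa is not None:
            write_volume(fx.dose_oa, fdir / "dose_oa.nii.gz")
            entry["dose_oa"] = f"{sub}/dose_oa.nii.gz"
        if fx.dose_conv is not None:
            write_volume(fx.dose_conv, fdir / "dose_conv.nii.gz")
            entry["dose_conv"] = f"{sub}/dose_conv.nii.gz"
        manifest["fractions"].append(entry)
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def load_case(case_dir: str | Path) -> PatientCase:
    """Load a patient case from its manifest."""
    case_dir = Path(case_dir)
    with open(case_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    params_dict = manifest["params"]
    for key in ("bladder_volume_range", "rectum_volume_range", "drift_mm_per_fraction"):
        params_dict[key] = tuple(params_dict[key])
    params = PhantomParams(**params_dict)
    rel = lambda p: case_dir / p
    case = PatientCase(
        patient_id=manifest["patient_id"],
        params=params,
        ref_image=read_volume(rel(manifest["ref"]["image"])),
        ref_structures={
            lab: read_mask(rel(p), lab) for lab, p in manifest["ref"]["structures"].items()
        },
        ref_dose=read_volume(rel(manifest["ref"]["dose"])),
        dose_model=DoseModelParams(**manifest["dose_model"]),
    )
    for entry in manifest["fractions"]:
        fx = FractionRecord(
            index=int(entry["index"]),
            image=read_volume(rel(entry["image"])),
            structures={lab: read_mask(rel(p), lab) for lab, p in entry["structures"].items()},
            gt_dvf_ref_to_fx=read_vector_field(rel(entry["gt_dvf"])),
            applied_shift=tuple(entry["applied_shift"]),
        )
        if "dose_oa" in entry:
            fx.dose_oa = read_volume(rel(entry["dose_oa"]))
        if "dose_conv" in entry:
            fx.dose_conv = read_volume(rel(entry["dose_conv"]))
        case.fractions.append(fx)
    return case


def write_cohort(cases: list[PatientCase], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for case in cases:
        write_case(case, out)
        ids.append(case.patient_id)
    index_path = out / "cohort.yaml"
    with open(index_path, "w") as fh:
        yaml.safe_dump({"patients": ids}, fh)
    return index_path


def load_cohort(cohort_dir: str | Path) -> list[PatientCase]:
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "cohort.yaml") as fh:
        index = yaml.safe_load(fh)
    return [load_case(cohort_dir / pid) for pid in index["patients"]]
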