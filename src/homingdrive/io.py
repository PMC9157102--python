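"""Table and configuration I/O.

All tables are comma-delimited UTF-8 with mandatory headers.  Generation
indices are 0-based, with generation 0 the founder release.  Parameter
files are flat YAML key-value mappings whose keys match the
:class:`~homingdrive.params.DriveParams` and
:class:`~homingdrive.params.FitnessSpec` field names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import DRIVE_PAIRS, OFFTARGET_PAIRS, Sex, genotype_index
from .inference import CageObservations, FitResult
from .model import PopulationState
from .params import DriveParams, FitnessModel, FitnessSpec

__all__ = [
    "TableFormatError",
    "read_cage_observations",
    "write_cage_observations",
    "read_params",
    "write_params",
    "read_population_state",
    "write_population_state",
    "write_fit_result",
    "read_fit_result",
    "read_cross_counts",
    "read_sterility_counts",
]


class TableFormatError(ValueError):
    """A delimited input table violates the documented format."""


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")


def read_cage_observations(path, label: str | None = None) -> CageObservations:
    """Read `generation,carriers,noncarriers` counts for one cage.

    Validates non-negative integer counts and consecutive generations,
    reporting the offending row on failure.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"generation", "carriers", "noncarriers"}, path)
    for i, row in df.iterrows():
        for col in ("generation", "carriers", "noncarriers"):
            v = row[col]
            if pd.isna(v) or float(v) != int(v) or int(v) < 0:
                raise TableFormatError(
                    f"{path}: row {i + 1}: {col} must be a non-negative integer, got {v!r}"
                )
    gens = df["generation"].to_numpy(dtype=int)
    jumps = np.nonzero(np.diff(gens) != 1)[0]
    if len(jumps):
        raise TableFormatError(
            f"{path}: row {jumps[0] + 2}: generations must be consecutive "
            f"(found {gens[jumps[0]]} -> {gens[jumps[0] + 1]})"
        )
    return CageObservations.from_frame(df, label=label or path.stem)


def write_cage_observations(obs: CageObservations, path) -> None:
    obs.to_frame().to_csv(path, index=False)


def read_params(path) -> tuple[DriveParams, FitnessSpec]:
    """Read drive rates and an optional fitness model from flat YAML.

    Unknown keys are rejected.  Keys ``model`` and ``homozygote_fitness``
    configure the :class:`FitnessSpec` (defaulting to neutral); all other
    keys must be :class:`DriveParams` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TableFormatError(f"{path}: parameter file must be a flat key-value mapping")
    drive_fields = {f.name for f in dataclasses.fields(DriveParams)}
    fit_kwargs, drive_kwargs = {}, {}
    for key, value in raw.items():
        if key in ("model", "homozygote_fitness"):
            fit_kwargs[key] = value
        elif key in drive_fields:
            drive_kwargs[key] = value
        else:
            raise TableFormatError(f"{path}: unknown parameter key {key!r}")
    if "model" in fit_kwargs:
        fit_kwargs["model"] = FitnessModel(fit_kwargs["model"])
    return DriveParams(**drive_kwargs), FitnessSpec(**fit_kwargs)


def write_params(p: DriveParams, spec: FitnessSpec, path) -> None:
    data = dataclasses.asdict(p)
    data["model"] = spec.model.value
    data["homozygote_fitness"] = spec.homozygote_fitness
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_population_state(state: PopulationState, path) -> None:
    """Serialize a state as genotype_drive,genotype_offtarget,sex,frequency."""
    rows = []
    for sex, arr in ((Sex.FEMALE, state.female), (Sex.MALE, state.male)):
        for dp in DRIVE_PAIRS:
            for op in OFFTARGET_PAIRS:
                rows.append(
                    {
                        "genotype_drive": "/".join(a.name for a in dp),
                        "genotype_offtarget": "/".join(a.name for a in op),
                        "sex": sex.name.lower(),
                        "frequency": arr[genotype_index(dp, op)],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population_state(path) -> PopulationState:
    df = pd.read_csv(path, comment="#")
    _require_columns(
        df, {"genotype_drive", "genotype_offtarget", "sex", "frequency"}, path
    )
    f = np.zeros(len(DRIVE_PAIRS) * len(OFFTARGET_PAIRS))
    m = np.zeros_like(f)
    for i, row in df.iterrows():
        try:
            dp = tuple(row["genotype_drive"].split("/"))
            op = tuple(row["genotype_offtarget"].split("/"))
            from .genotypes import DriveAllele, OffTargetAllele

            idx = genotype_index(
                tuple(DriveAllele[a] for a in dp), tuple(OffTargetAllele[a] for a in op)
            )
            sex = Sex.FEMALE if row["sex"].lower().startswith("f") else Sex.MALE
        except (KeyError, AttributeError) as exc:
            raise TableFormatError(f"{path}: row {i + 1}: {exc}") from exc
        (f if sex is Sex.FEMALE else m)[idx] += float(row["frequency"])
    return PopulationState(f, m)


def write_fit_result(result: FitResult, path) -> None:
    """Flat key-value report of a fit (one `key,value` row per field)."""
    with open(path, "w") as fh:
        fh.write("key,value\n")
        for key, value in result.to_dict().items():
            fh.write(f"{key},{value}\n")


def read_fit_result(path) -> dict:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"key", "value"}, path)
    out = {}
    for _, row in df.iterrows():
        key, value = row["key"], row["value"]
        if key == "model":
            out[key] = str(value)
        elif key == "n_transitions":
            out[key] = int(value)
        else:
            out[key] = float(value)
    return out


def read_cross_counts(path):
    """Read `parent_sex,with_drive,without_drive[,vial]` cross tables.

    Returns a list of :class:`~homingdrive.cross_stats.CrossCounts`, one
    per parent sex, with per-vial batches preserved when a vial column is
    present.
    """
    from .cross_stats import CrossCounts

    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"parent_sex", "with_drive", "without_drive"}, path)
    out = []
    for sex, grp in df.groupby("parent_sex", sort=False):
        batches = None
        if "vial" in df.columns:
            batches = [
                (int(r["with_drive"]), int(r["without_drive"])) for _, r in grp.iterrows()
            ]
        out.append(
            CrossCounts(
                parent_sex=str(sex),
                offspring_with_drive=int(grp["with_drive"].sum()),
                offspring_without_drive=int(grp["without_drive"].sum()),
                batches=batches,
            )
        )
    return out


def read_sterility_counts(path):
    """Read a one-row `sterile,assessed,baseline_sterile,baseline_assessed` table."""
    from .cross_stats import SterilityCounts

    df = pd.read_csv(path, comment="#")
    _require_columns(
        df, {"sterile", "assessed", "baseline_sterile", "baseline_assessed"}, path
    )
    row = df.iloc[0]
    return SterilityCounts(
        sterile=int(row["sterile"]),
        assessed=int(row["assessed"]),
        baseline_sterile=int(row["baseline_sterile"]),
        baseline_assessed=int(row["baseline_assessed"]),
    )
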