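"""Readers and writers for the package's plain-text formats.

* sequences: one ``ID<TAB>HPHHP...`` record per line, or FASTA;
* PMF: 3-column text (r, u/kBT, SE) with ``#`` comments;
* contact map: N x N matrix text with a header comment carrying
  sequence_id, rc and n_configs; validated on read;
* feature table / spectrum: CSV;
* report: JSON;
* trajectory: XYZ, element = monomer label.

Machine files use 17-significant-digit floats so a rerun with the same
config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMap, validate_contact_matrix
from .errors import ValidationError
from .model import HPSequence
from .sampler import PMFProfile, SampleEnsemble, well_bounds_from_profile

__all__ = [
    "read_sequences",
    "write_sequences",
    "read_pmf",
    "write_pmf",
    "read_contact_map",
    "write_contact_map",
    "read_feature_table",
    "write_feature_table",
    "write_spectrum",
    "write_report",
    "write_xyz",
]

FLOAT_FMT = "%.17g"


def read_sequences(path: str | Path) -> list[HPSequence]:
    """Read sequences from tab-separated lines or FASTA (auto-detected)."""
    text = Path(path).read_text()
    lines = text.splitlines()
    seqs: list[HPSequence] = []
    if any(line.startswith(">") for line in lines):
        current_id, chunks = None, []
        for line in lines:
            if line.startswith(">"):
                if current_id is not None:
                    seqs.append(HPSequence(current_id, "".join(chunks)))
                current_id = line[1:].split()[0]
                chunks = []
            elif line.strip():
                chunks.append(line.strip())
        if current_id is not None:
            seqs.append(HPSequence(current_id, "".join(chunks)))
        return seqs
    for ln, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValidationError(f"{path}:{ln}: expected 'ID<TAB>SEQUENCE'")
        seqs.append(HPSequence(parts[0], parts[1].strip()))
    return seqs


def write_sequences(seqs: list[HPSequence], path: str | Path, fasta: bool = False) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            if fasta:
                fh.write(f">{s.id}\n{s.monomers}\n")
            else:
                fh.write(f"{s.id}\t{s.monomers}\n")


def write_pmf(pmf: PMFProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# r  u_over_kBT  standard_error  correlated_error\n")
        fh.write(
            f"# well_bounds = {pmf.well_bounds[0]!r} {pmf.well_bounds[1]!r}\n"
        )
        for r, u, se, ce in zip(
            pmf.r_grid, pmf.u_over_kBT, pmf.statistical_error, pmf.correlated_error
        ):
            fh.write(f"{r:.17g} {u:.17g} {se:.17g} {ce:.17g}\n")


def read_pmf(path: str | Path) -> PMFProfile:
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed PMF file: {exc}") from None
    if data.shape[1] not in (3, 4):
        raise ValidationError(f"{path}: expected columns (r, u/kBT, SE[, corr])")
    r, u, se = data.T[:3]
    corr = data.T[3] if data.shape[1] == 4 else None
    well, u_min = well_bounds_from_profile(r, u)
    return PMFProfile(
        r_grid=r,
        u_over_kBT=u,
        statistical_error=se,
        well_bounds=well,
        u_min=u_min,
        correlated_error=corr,
    )


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# sequence_id={cmap.sequence_id} rc={cmap.rc:.17g} "
            f"n_configs={cmap.n_configs}\n"
        )
        np.savetxt(fh, cmap.matrix, fmt=FLOAT_FMT)


def read_contact_map(path: str | Path) -> ContactMap:
    path = Path(path)
    header = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                key, val = token.split("=", 1)
                header[key] = val
    try:
        matrix = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed matrix: {exc}") from None
    try:
        validate_contact_matrix(matrix)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    return ContactMap(
        matrix=matrix,
        n_configs=int(header.get("n_configs", 0)),
        rc=float(header.get("rc", "nan")),
        sequence_id=header.get("sequence_id", path.stem),
    )


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_table(
    path: str | Path, require_label: bool = True
) -> pd.DataFrame:
    df = pd.read_csv(path)
    if require_label:
        if "label" not in df.columns:
            raise ValidationError(f"{path}: missing 'label' column")
        missing = df.index[df["label"].isna()]
        if len(missing):
            ids = (
                df.loc[missing, "sequence_id"].tolist()
                if "sequence_id" in df.columns
                else missing.tolist()
            )
            raise ValidationError(f"{path}: missing label for rows {ids}")
    return df


def write_spectrum(spec, path: str | Path) -> None:
    """CSV export: wavenumber, aggregated power, and both EV orderings."""
    from .spectral import ev_curves

    curves = ev_curves(spec)
    df = pd.DataFrame(
        {
            "k": spec.unique_wavenumbers,
            "aggregated_power": spec.aggregated_power,
            "cumulative_EV_by_k": curves.ev_by_wavenumber,
            "cumulative_EV_by_power": curves.ev_by_power,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_xyz(ensemble: SampleEnsemble, path: str | Path) -> None:
    """XYZ trajectory, one frame per retained snapshot, element = label."""
    states = ensemble.states
    if states.ndim == 3:
        states = states[:, None, :, :]
    labels = (
        ensemble.sequence.monomers
        if ensemble.sequence is not None
        else "X" * states.shape[2]
    )
    with open(path, "w") as fh:
        for frame in states:
            n_atoms = frame.shape[0] * frame.shape[1]
            fh.write(f"{n_atoms}\nframe\n")
            for chain in frame:
                for label, (x, y, z) in zip(labels, chain):
                    fh.write(f"{label} {x:.8f} {y:.8f} {z:.8f}\n")
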