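"""Plain-text I/O and connectome preparation.

All on-disk formats are whitespace- or comma-delimited text: matrices as
TSV (N rows x N columns, optional one-line header), BOLD as T x N TSV with
the repetition time in a JSON sidecar, parcellations as a TSV with columns
``label``, ``hemisphere``, ``partner_index`` plus a separate N x K network
membership TSV, and cohort manifests as JSON. Indices are 0-based
everywhere.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SC_CEILING, BoldSeries, FCMatrix, Parcellation, StateDataset, StructuralConnectome
from .errors import ConfigurationError, ParseError

_DELIM = re.compile(r"[,\s]+")


def read_matrix(path, expected_n: int | None = None) -> np.ndarray:
    """Read a numeric matrix from delimited text.

    Accepts whitespace- and/or comma-delimited rows and an optional single
    non-numeric header line. Raises :class:`ParseError` naming the
    offending line for ragged rows, non-numeric tokens, or (when
    ``expected_n`` is given) a column-count mismatch.
    """
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = [t for t in _DELIM.split(line.strip()) if t]
            if not tokens:
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                if lineno == 1 and not rows:
                    continue  # tolerated single header line
                raise ParseError(f"{path}: non-numeric token at line {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} columns, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no numeric rows found")
    mat = np.asarray(rows, dtype=float)
    if expected_n is not None and mat.shape[1] != expected_n:
        raise ParseError(
            f"{path}: expected {expected_n} columns, found {mat.shape[1]}"
        )
    return mat


def write_matrix(path, matrix: np.ndarray, header: list[str] | None = None) -> None:
    """Write a matrix as TSV with full double precision (round-trips exactly)."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in np.atleast_2d(matrix):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_bold(path, sidecar: str | Path | None = None, tr_seconds: float | None = None) -> BoldSeries:
    """Read a T x N BOLD TSV; TR comes from ``tr_seconds`` or a JSON sidecar
    (``{"tr_seconds": ...}``, default ``<path>.json``)."""
    if tr_seconds is None:
        sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
        if not sidecar.exists():
            raise ParseError(f"no TR given and sidecar {sidecar} not found")
        tr_seconds = float(json.loads(sidecar.read_text())["tr_seconds"])
    return BoldSeries(read_matrix(path), tr_seconds=tr_seconds)


def write_bold(path, series: BoldSeries) -> None:
    write_matrix(path, series.samples)
    Path(str(path) + ".json").write_text(json.dumps({"tr_seconds": series.tr_seconds}))


def read_parcellation(path, rsn_path=None) -> Parcellation:
    """Read a parcellation TSV (columns label, hemisphere, partner_index;
    partner -1 for none) and optionally an N x K membership TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "hemisphere", "partner_index"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: parcellation needs columns {sorted(required)}")
    membership = None
    if rsn_path is not None:
        membership = read_matrix(rsn_path, expected_n=None)
        if membership.shape[0] != len(df):
            raise ParseError(
                f"{rsn_path}: {membership.shape[0]} rows for {len(df)} regions"
            )
    return Parcellation(
        region_labels=list(df["label"].astype(str)),
        hemisphere=df["hemisphere"].to_numpy(),
        homotopic_partner=df["partner_index"].to_numpy(dtype=int),
        rsn_membership=membership,
    )


def write_parcellation(path, parc: Parcellation, rsn_path=None) -> None:
    pd.DataFrame(
        {
            "label": parc.region_labels,
            "hemisphere": parc.hemisphere,
            "partner_index": parc.homotopic_partner,
        }
    ).to_csv(path, sep="\t", index=False)
    if rsn_path is not None and parc.rsn_membership is not None:
        write_matrix(rsn_path, parc.rsn_membership)


def enumerate_homotopic_pairs(parc: Parcellation) -> list[tuple[int, int]]:
    """List each homotopic pair once, lower index first, in index order.

    Raises :class:`ConfigurationError` naming the first lateral (L/R)
    region that lacks a partner.
    """
    pairs = []
    for j, p in enumerate(parc.homotopic_partner):
        if p < 0:
            if parc.hemisphere[j] in ("L", "R"):
                raise ConfigurationError(
                    f"lateral region {parc.region_labels[j]!r} has no homotopic partner"
                )
            continue
        if j < p:
            pairs.append((j, int(p)))
    return pairs


def scale_connectome(conn: StructuralConnectome, ceiling: float = SC_CEILING) -> StructuralConnectome:
    """Rescale coupling weights so the maximum entry equals ``ceiling``.

    Linear scaling preserves entry ratios; an all-zero matrix cannot be
    scaled and raises.
    """
    w = conn.weights
    wmax = w.max()
    if wmax <= 0:
        raise ConfigurationError("cannot scale an all-zero connectome")
    return StructuralConnectome(w * (ceiling / wmax), scaled=np.isclose(ceiling, SC_CEILING))


def symmetrize(weights: np.ndarray) -> np.ndarray:
    """Average a (possibly seed-direction-dependent) matrix with its transpose."""
    w = np.asarray(weights, dtype=float)
    return 0.5 * (w + w.T)


def load_connectome(path, expected_n: int | None = None, scale: bool = True) -> StructuralConnectome:
    """Read a connectome TSV, symmetrize, zero the diagonal, and (by
    default) scale to the weak-coupling ceiling.

    Probabilistic-tractography matrices are asymmetric because streamline
    seeding is directional; the model uses a single coupling per edge, so
    the loader averages the matrix with its transpose. No streamline-count
    threshold is applied.
    """
    w = symmetrize(read_matrix(path, expected_n=expected_n))
    np.fill_diagonal(w, 0.0)
    conn = StructuralConnectome(w)
    return scale_connectome(conn) if scale else conn


def write_fc(path, fc: FCMatrix) -> None:
    write_matrix(path, fc.values)


def read_fc(path, kind: str = "pearson", expected_n: int | None = None) -> FCMatrix:
    return FCMatrix(read_matrix(path, expected_n=expected_n), kind=kind)


def load_cohort_manifest(path) -> tuple[dict[str, StateDataset], dict[str, dict]]:
    """Load a cohort manifest JSON.

    The manifest lists states with per-subject file paths (BOLD TSVs with
    sidecars, or FC TSVs), the name of each state's wakefulness baseline,
    and optional ``route``/``depth`` annotations::

        {"tr_seconds": 2.0,
         "states": {"W":  {"subjects": ["W_s0.tsv", ...], "wake_baseline": null,
                           "route": "sleep", "depth": 0},
                    "N3": {"subjects": [...], "wake_baseline": "W", ...}}}

    Relative paths resolve against the manifest's directory. Returns the
    datasets plus the per-state metadata.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    tr = spec.get("tr_seconds")
    datasets: dict[str, StateDataset] = {}
    meta: dict[str, dict] = {}
    for name, entry in spec["states"].items():
        subjects = []
        for sub in entry["subjects"]:
            p = path.parent / sub
            if str(sub).endswith(".fc.tsv") or entry.get("kind") == "fc":
                subjects.append(read_fc(p))
            else:
                subjects.append(read_bold(p, tr_seconds=tr))
        datasets[name] = StateDataset(state_name=name, subjects=subjects)
        meta[name] = {
            "wake_baseline": entry.get("wake_baseline"),
            "route": entry.get("route", "default"),
            "depth": entry.get("depth", 0),
        }
    for name, entry in meta.items():
        wb = entry["wake_baseline"]
        if wb is not None:
            if wb not in datasets:
                raise ConfigurationError(f"state {name!r}: unknown wake baseline {wb!r}")
            datasets[name].wake_baseline = datasets[wb]
        elif entry["depth"] != 0:
            raise ConfigurationError(f"non-wake state {name!r} needs a wake baseline")
    return datasets, meta
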