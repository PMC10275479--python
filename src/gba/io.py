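"""Model and result file formats.

Models are stored as TOML with an embedded CSV matrix block::

    [model]
    name = "A"
    format = "gba-model-v1"
    rho = 1.0

    [reactants]        # id = kind ("m" | "a"), in row order
    m = "m"
    a = "a"

    [reactions]        # id = kind ("s" | "e" | "r"), in column order
    s = "s"
    r = "r"

    [external]         # id = concentration
    glc_ext = 1.0

    [matrix]           # inline CSV (or file = "path.csv" relative to the model)
    csv = (a TOML multi-line string holding:)
    reactants,s,r
    m,1.0,-1.0
    a,0.0,1.0

    [kinetics.s]
    law = "irreversible_mm"
    kcat_fwd = 1.0
    substrates = ["glc_ext"]
    [kinetics.s.km]
    glc_ext = 1.0

All reals are written with ``repr`` (shortest round-trip decimal), so
``read_model(write_model(m))`` reproduces every entry bit-exactly.
Optimization results serialize to JSON with full provenance (package
version, model hash, seed, tolerances, per-start table).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ModelFormatError
from .kinetics import KineticLaw
from .model import GBAModel, require_valid

FORMAT_TAG = "gba-model-v1"


import re

_BARE_KEY = re.compile(r"[A-Za-z0-9_-]+\Z")


def _key(k: str) -> str:
    return k if _BARE_KEY.match(k) else json.dumps(k)


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(i) for i in v) + "]"
    raise TypeError(f"cannot format {type(v)}")


def _matrix_csv(model) -> str:
    buf = _io.StringIO()
    buf.write("reactants," + ",".join(model.reaction_ids) + "\n")
    for i, rid in enumerate(model.reactant_ids):
        buf.write(rid + "," + ",".join(repr(float(v)) for v in model.M[i]) + "\n")
    return buf.getvalue()


def model_to_text(model: GBAModel) -> str:
    """Serialize a validated model to the TOML model-file text."""
    require_valid(model)
    lines = ["[model]"]
    lines.append(f"name = {_fmt(model.name or 'unnamed')}")
    lines.append(f"format = {_fmt(FORMAT_TAG)}")
    lines.append(f"rho = {_fmt(model.rho)}")
    lines.append("")
    lines.append("[reactants]")
    for rid, kind in zip(model.reactant_ids, model.reactant_kinds):
        lines.append(f"{_key(rid)} = {_fmt(kind)}")
    lines.append("")
    lines.append("[reactions]")
    for rid, kind in zip(model.reaction_ids, model.reaction_kinds):
        lines.append(f"{_key(rid)} = {_fmt(kind)}")
    lines.append("")
    lines.append("[external]")
    for xid, val in model.x.items():
        lines.append(f"{_key(xid)} = {_fmt(float(val))}")
    lines.append("")
    lines.append("[matrix]")
    lines.append('csv = """')
    lines.append(_matrix_csv(model) + '"""')
    for rid in model.reaction_ids:
        law = model.kinetics[rid]
        lines.append("")
        lines.append(f"[kinetics.{_key(rid)}]")
        lines.append(f"law = {_fmt(law.law_kind)}")
        lines.append(f"kcat_fwd = {_fmt(law.kcat_fwd)}")
        if law.kcat_bwd:
            lines.append(f"kcat_bwd = {_fmt(law.kcat_bwd)}")
        if law.substrates:
            lines.append(f"substrates = {_fmt(list(law.substrates))}")
        if law.products:
            lines.append(f"products = {_fmt(list(law.products))}")
        if law.km:
            lines.append(f"[kinetics.{_key(rid)}.km]")
            for r, k in law.km.items():
                lines.append(f"{_key(r)} = {_fmt(float(k))}")
        if law.ki:
            lines.append(f"[kinetics.{_key(rid)}.ki]")
            for r, k in law.ki.items():
                lines.append(f"{_key(r)} = {_fmt(float(k))}")
    return "\n".join(lines) + "\n"


def write_model(model: GBAModel, path) -> None:
    Path(path).write_text(model_to_text(model), encoding="utf-8")


def model_hash(model: GBAModel) -> str:
    """Stable content hash of a model (sha256 of its canonical file text)."""
    return hashlib.sha256(model_to_text(model).encode()).hexdigest()


def _parse_law(rid: str, sec: dict) -> KineticLaw:
    try:
        law_kind = sec["law"]
    except KeyError:
        raise ModelFormatError(f"kinetics section of {rid!r} missing 'law'")
    known = {"law", "kcat_fwd", "kcat_bwd", "substrates", "products", "km", "ki"}
    extra = set(sec) - known
    if extra:
        raise ModelFormatError(f"unknown kinetics keys for {rid!r}: {sorted(extra)}")
    try:
        return KineticLaw(
            law_kind=law_kind,
            kcat_fwd=float(sec.get("kcat_fwd", 0.0)),
            kcat_bwd=float(sec.get("kcat_bwd", 0.0)),
            km={k: float(v) for k, v in sec.get("km", {}).items()},
            ki={k: float(v) for k, v in sec.get("ki", {}).items()},
            substrates=tuple(sec.get("substrates", ())),
            products=tuple(sec.get("products", ())),
        )
    except Exception as exc:
        raise ModelFormatError(f"bad kinetic law for {rid!r}: {exc}") from exc


def read_model(path) -> GBAModel:
    """Read and validate a model file; raises on parse or validation failure."""
    path = Path(path)
    try:
        doc = tomllib.loads(path.read_text(encoding="utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    for section in ("model", "reactants", "reactions", "matrix"):
        if section not in doc:
            raise ModelFormatError(f"{path}: missing [{section}] section")

    mat = doc["matrix"]
    if "csv" in mat:
        M_df = pd.read_csv(_io.StringIO(mat["csv"]), index_col=0)
    elif "file" in mat:
        M_df = pd.read_csv(path.parent / mat["file"], index_col=0)
    else:
        raise ModelFormatError(f"{path}: [matrix] needs 'csv' or 'file'")

    reactants = doc["reactants"]
    reactions = doc["reactions"]
    if list(M_df.index) != list(reactants) or list(M_df.columns) != list(reactions):
        raise ModelFormatError(
            f"{path}: matrix row/column labels disagree with "
            "[reactants]/[reactions] order"
        )
    kin_sections = doc.get("kinetics", {})
    missing = [r for r in reactions if r not in kin_sections]
    if missing:
        raise ModelFormatError(f"{path}: missing kinetics for {missing}")
    kinetics = {rid: _parse_law(rid, sec) for rid, sec in kin_sections.items()}

    model = GBAModel(
        reactant_ids=tuple(reactants),
        reactant_kinds=tuple(reactants.values()),
        reaction_ids=tuple(reactions),
        reaction_kinds=tuple(reactions.values()),
        M=M_df.to_numpy(dtype=float),
        rho=float(doc["model"].get("rho", 0.0)),
        x={k: float(v) for k, v in doc.get("external", {}).items()},
        kinetics=kinetics,
        name=str(doc["model"].get("name", path.stem)),
    )
    return require_valid(model)


def result_to_dict(result, model: GBAModel) -> dict:
    """JSON-serializable record of an optimization, sufficient to re-run it."""
    return {
        "tool": "gba",
        "version": __version__,
        "model_name": model.name,
        "model_hash": model_hash(model),
        "seed": result.seed,
        "n_starts": result.n_starts,
        "tol": result.tol,
        "tol_active": result.tol_active,
        "mu_star": result.mu_star,
        "f_star": {rid: float(v) for rid, v in zip(model.reaction_ids, result.f_star)},
        "lambda": result.lambda_,
        "theta": {rid: float(v) for rid, v in zip(model.reaction_ids, result.theta)},
        "active": {rid: bool(v) for rid, v in zip(model.reaction_ids, result.active)},
        "active_rank": result.active_rank,
        "full_column_rank": result.full_column_rank,
        "kkt_residual": result.kkt_residual,
        "boundary_metabolites": list(result.boundary_metabolites),
        "starts": [
            {
                "index": s.index,
                "f0": [float(v) for v in s.f0],
                "f_opt": None if s.f_opt is None else [float(v) for v in s.f_opt],
                "mu": None if np.isnan(s.mu) else float(s.mu),
                "status": s.status,
            }
            for s in result.starts
        ],
    }


def write_result(result, model: GBAModel, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, model), indent=2),
                          encoding="utf-8")


def read_result_f(path, model: GBAModel) -> np.ndarray:
    """Load the optimal flux fractions from a result JSON, aligned to the model."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        fmap = doc["f_star"]
        return np.array([float(fmap[rid]) for rid in model.reaction_ids])
    except KeyError as exc:
        raise ModelFormatError(f"{path}: not a gba result file ({exc})") from exc
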