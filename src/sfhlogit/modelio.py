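"""Plain-text model files and on-disk layout for keys and encrypted data.

Models are key=value text (one coefficient per line, covariate names
preserved).  Keys and ciphertexts use the fixed-width binary format of
:mod:`sfhlogit.fv`; an encrypted dataset is a directory holding a JSON
manifest plus one ``.ct`` file per (record, value, CRT factor).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import fv
from .encoding import EncodingConfig
from .encrypted import EncryptedDataset, EncValue, _Meta
from .fv import Ciphertext, FVParams, KeyMaterial
from .sfh import ModelVector

__all__ = [
    "save_model",
    "load_model",
    "save_keys",
    "load_secret_key",
    "load_public_key",
    "load_relin_key",
    "save_encrypted_dataset",
    "load_encrypted_dataset",
    "save_encrypted_model",
    "load_encrypted_model",
]


def save_model(model: ModelVector, path, names: list[str] | None = None) -> None:
    if names is None:
        names = [f"x{j}" for j in range(1, len(model))]
    if len(names) != len(model) - 1:
        raise ValueError("one name per covariate required")
    lines = [f"intercept={float(model.beta[0])!r}"]
    lines += [f"{n}={float(v)!r}" for n, v in zip(names, model.beta[1:])]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> tuple[ModelVector, list[str]]:
    beta, names = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key=value")
        key, val = line.split("=", 1)
        try:
            beta.append(float(val))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: bad coefficient {val!r}") from exc
        names.append(key.strip())
    if not beta or names[0] != "intercept":
        raise ValueError(f"{path}: first entry must be the intercept")
    return ModelVector(np.array(beta)), names[1:]


def save_keys(km: KeyMaterial, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "secret.key").write_bytes(fv.serialize_secret_key(km))
    (outdir / "public.key").write_bytes(fv.serialize_public_key(km))
    (outdir / "relin.key").write_bytes(fv.serialize_relin_key(km))


def load_secret_key(keydir, params: FVParams) -> list[int]:
    return fv.deserialize_secret_key(
        (Path(keydir) / "secret.key").read_bytes(), params
    )


def load_public_key(keydir, params: FVParams):
    return fv.deserialize_public_key(
        (Path(keydir) / "public.key").read_bytes(), params
    )


def load_relin_key(keydir, params: FVParams):
    return fv.deserialize_relin_key(
        (Path(keydir) / "relin.key").read_bytes(), params
    )


def _write_value(ev: EncValue, outdir: Path, stem: str, manifest_vals: list) -> None:
    files = []
    for fi, ct in enumerate(ev.cts):
        name = f"{stem}.f{fi}.ct"
        (outdir / name).write_bytes(fv.serialize_ciphertext(ct))
        files.append(name)
    manifest_vals.append(
        {"stem": stem, "files": files, "emax": ev.meta.emax, "emin": ev.meta.emin}
    )


def _read_value(entry: dict, outdir: Path, fparams: list[FVParams]) -> EncValue:
    cts = [
        fv.deserialize_ciphertext((outdir / name).read_bytes(), fp)
        for name, fp in zip(entry["files"], fparams)
    ]
    return EncValue(cts=cts, meta=_Meta(entry["emax"], entry["emin"]))


def save_encrypted_dataset(enc: EncryptedDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values: list = []
    for i, row in enumerate(enc.x):
        for j, ev in enumerate(row):
            _write_value(ev, outdir, f"x{i:05d}_{j:03d}", values)
    for i, ev in enumerate(enc.y):
        _write_value(ev, outdir, f"y{i:05d}", values)
    manifest = enc.manifest()
    manifest["values"] = values
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_encrypted_dataset(
    outdir, cfg: EncodingConfig, params: FVParams
) -> EncryptedDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    if manifest["D"] != params.D or tuple(manifest["t_factors"]) != cfg.t_factors:
        raise ValueError("manifest does not match the supplied parameters")
    fparams = [params.with_t(ti) for ti in cfg.t_factors]
    N, d = manifest["N"], manifest["d"]
    by_stem = {e["stem"]: e for e in manifest["values"]}
    x = [
        [_read_value(by_stem[f"x{i:05d}_{j:03d}"], outdir, fparams) for j in range(d)]
        for i in range(N)
    ]
    y = [_read_value(by_stem[f"y{i:05d}"], outdir, fparams) for i in range(N)]
    return EncryptedDataset(x=x, y=y, N=N, d=d, cfg=cfg, params=params)


def save_encrypted_model(enc_beta: list[EncValue], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values: list = []
    for k, ev in enumerate(enc_beta):
        _write_value(ev, outdir, f"beta{k:03d}", values)
    (outdir / "model_manifest.json").write_text(
        json.dumps({"n_coeffs": len(enc_beta), "values": values}, indent=1)
    )


def load_encrypted_model(
    outdir, cfg: EncodingConfig, params: FVParams
) -> list[EncValue]:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "model_manifest.json").read_text())
    fparams = [params.with_t(ti) for ti in cfg.t_factors]
    by_stem = {e["stem"]: e for e in manifest["values"]}
    return [
        _read_value(by_stem[f"beta{k:03d}"], outdir, fparams)
        for k in range(manifest["n_coeffs"])
    ]
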