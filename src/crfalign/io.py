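"""Readers and writers for the package's plain-text formats.

* residue-track TSV: one protein per file, one row per residue.  Query
  files carry secondary-structure and solvent-accessibility state
  probabilities (columns ``ss3_H ss3_E ss3_C sa_B sa_M sa_E``); template
  files carry a one-hot observed secondary-structure row and a single
  observed RSA column (``sa_rsa``) instead of the three probabilities.
* pair feature-grid TSV: one query-template pair per file, one row per
  lattice cell ``(x, y)`` with the 4 match and 2 x 3 insertion channels
  (the form the synthetic generator emits).
* alignment TSV and aligned FASTA: see :mod:`crfalign.lattice`.
* model JSON: factor bank, normalizer statistics and training metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__
from .factors import bank_from_dict, bank_to_dict
from .features import FeatureTracks, Normalizer, ResidueTrack, SS3_CLASSES
from .training import EpochRecord, TrainConfig, TrainedModel

_PROFILE_COLS = [f"p{i}" for i in range(1, 21)]
_QUERY_COLS = (["idx", "aa"] + _PROFILE_COLS
               + ["ss3_H", "ss3_E", "ss3_C", "sa_B", "sa_M", "sa_E", "disorder"])
_TEMPLATE_COLS = (["idx", "aa"] + _PROFILE_COLS
                  + ["ss3_H", "ss3_E", "ss3_C", "sa_rsa", "disorder"])


def write_residue_track(track: ResidueTrack, path: str | Path) -> None:
    cols = _TEMPLATE_COLS if track.is_template else _QUERY_COLS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(len(track)):
            row: list[str] = [str(i + 1), track.sequence[i]]
            row += [f"{v:.9g}" for v in track.profile[i]]
            if track.is_template:
                onehot = [0.0, 0.0, 0.0]
                onehot[SS3_CLASSES.index(track.ss3[i])] = 1.0
                row += [f"{v:.9g}" for v in onehot]
                row.append(f"{track.sa[i]:.9g}")
            else:
                row += [f"{v:.9g}" for v in track.ss3[i]]
                row += [f"{v:.9g}" for v in track.sa[i]]
            row.append(str(int(track.disorder[i])))
            fh.write("\t".join(row) + "\n")


def read_residue_track(path: str | Path) -> ResidueTrack:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header == _QUERY_COLS:
            is_template = False
        elif header == _TEMPLATE_COLS:
            is_template = True
        else:
            missing = set(_QUERY_COLS) - set(header)
            raise ValueError(f"{path}: unrecognized header; missing columns "
                             f"{sorted(missing) or 'none'}, got {header}")
        seq, profile, ss3, sa, disorder = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, "
                                 f"got {len(parts)}")
            seq.append(parts[1])
            profile.append([float(v) for v in parts[2:22]])
            ss3_row = [float(v) for v in parts[22:25]]
            if is_template:
                if abs(sum(ss3_row) - 1.0) > 1e-6 or max(ss3_row) != 1.0:
                    raise ValueError(f"{path}:{lineno}: template SS3 row must be one-hot")
                ss3.append(SS3_CLASSES[int(np.argmax(ss3_row))])
                sa.append(float(parts[25]))
                disorder.append(int(parts[26]))
            else:
                if abs(sum(ss3_row) - 1.0) > 1e-6:
                    raise ValueError(f"{path}:{lineno}: SS3 probabilities sum to "
                                     f"{sum(ss3_row):.6g}, expected 1")
                sa_row = [float(v) for v in parts[25:28]]
                if abs(sum(sa_row) - 1.0) > 1e-6:
                    raise ValueError(f"{path}:{lineno}: SA probabilities sum to "
                                     f"{sum(sa_row):.6g}, expected 1")
                ss3.append(ss3_row)
                sa.append(sa_row)
                disorder.append(int(parts[28]))
    return ResidueTrack(
        sequence="".join(seq),
        profile=np.array(profile),
        ss3="".join(ss3) if is_template else np.array(ss3),
        sa=np.array(sa),
        disorder=np.array(disorder, dtype=bool),
    )


_PAIR_COLS = (["x", "y"] + [f"m{i}" for i in range(1, 5)]
              + [f"qi{i}" for i in range(1, 4)] + [f"ti{i}" for i in range(1, 4)])


def write_pair_features(tracks: FeatureTracks, path: str | Path) -> None:
    dims = tracks.dims
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLS) + "\n")
        for x in range(1, dims.Lq + 1):
            for y in range(1, dims.Lt + 1):
                vals = np.concatenate([tracks.match_features[x - 1, y - 1],
                                       tracks.qins_features[x - 1, y - 1],
                                       tracks.tins_features[x - 1, y - 1]])
                fh.write(f"{x}\t{y}\t" + "\t".join(f"{v:.12g}" for v in vals) + "\n")


def read_pair_features(path: str | Path) -> FeatureTracks:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PAIR_COLS:
            raise ValueError(f"{path}: unrecognized pair-feature header {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_PAIR_COLS):
                raise ValueError(f"{path}:{lineno}: expected {len(_PAIR_COLS)} columns")
            rows.append([float(v) for v in parts])
    arr = np.array(rows)
    Lq, Lt = int(arr[:, 0].max()), int(arr[:, 1].max())
    if len(rows) != Lq * Lt:
        raise ValueError(f"{path}: expected {Lq * Lt} cells, got {len(rows)}")
    match = np.zeros((Lq, Lt, 4))
    qins = np.zeros((Lq, Lt, 3))
    tins = np.zeros((Lq, Lt, 3))
    for row in rows:
        x, y = int(row[0]) - 1, int(row[1]) - 1
        match[x, y] = row[2:6]
        qins[x, y] = row[6:9]
        tins[x, y] = row[9:12]
    return FeatureTracks(None, None, match, qins, tins)


FORMAT_VERSION = 1


def save_model(path: str | Path, model: TrainedModel) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "bank": bank_to_dict(model.bank),
        "normalizer": model.normalizer.to_dict(),
        "config": dataclasses.asdict(model.config),
        "selected_epoch": model.selected_epoch,
        "history": [dataclasses.asdict(r) for r in model.history],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version "
                         f"{doc.get('format_version')!r}")
    return TrainedModel(
        bank=bank_from_dict(doc["bank"]),
        normalizer=Normalizer.from_dict(doc["normalizer"]),
        config=TrainConfig(**doc["config"]),
        history=[EpochRecord(**r) for r in doc["history"]],
        selected_epoch=doc["selected_epoch"],
    )


def write_history_tsv(history: list[EpochRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss\ttrain_acc\tvalid_acc\n")
        for r in history:
            fh.write(f"{r.epoch}\t{r.loss:.10g}\t{r.train_accuracy:.6g}"
                     f"\t{r.valid_accuracy:.6g}\n")
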