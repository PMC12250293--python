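"""File formats: FASTA, peak tables, melt curves, assay configs, results.

All formats are plain text. Readers and writers are lossless round-trip
pairs; malformed input raises :class:`~paralogmeth.errors.ParseError`
naming the offending line.

* FASTA (multi-record, record id = sequence id) via Biopython.
* Peak tables: TSV with columns ``disp_index`` (1-based), ``nucleotide``,
  ``height``.
* Melt curves: TSV with a ``temperature`` column and one fluorescence
  column per sample.
* Assay configs and results: JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assay import AssayConfig, ParalogPair, Primers
from .errors import ParseError
from .hrm import MeltCurve
from .pyrogram import DispensationOrder, Pyrogram
from .sequences import NucleotideSequence

logger = logging.getLogger("paralogmeth")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA; lowercase bases are uppercased with a
    warning."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq)
        if bases != bases.upper():
            logger.warning("sequence %s contains lowercase bases; uppercasing",
                           rec.id)
        try:
            out.append(NucleotideSequence(id=rec.id, bases=bases.upper()))
        except Exception as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(path, sequences: Sequence[NucleotideSequence]) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------- peak tables

def write_peaks_tsv(path, pyrogram: Pyrogram) -> None:
    df = pd.DataFrame({
        "disp_index": range(1, len(pyrogram.dispensation) + 1),
        "nucleotide": list(pyrogram.dispensation.nucleotides),
        "height": pyrogram.heights,
    })
    df.to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> Pyrogram:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("disp_index", "nucleotide", "height"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r} (line 1)")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if int(row["disp_index"]) != i + 1:
            raise ParseError(f"{path}: line {line}: disp_index must run 1..N")
        if float(row["height"]) < 0:
            raise ParseError(f"{path}: line {line}: negative peak height "
                             f"{row['height']}")
    disp = DispensationOrder("".join(str(n) for n in df["nucleotide"]))
    return Pyrogram(dispensation=disp,
                    heights=tuple(float(h) for h in df["height"]))


# ----------------------------------------------------------- melt curves

def write_melt_tsv(path, curves: Sequence[MeltCurve]) -> None:
    if not curves:
        raise ParseError("no melt curves to write")
    t0 = curves[0].temperatures
    for c in curves:
        if c.temperatures != t0:
            raise ParseError("all curves in one table must share the grid")
    data = {"temperature": t0}
    for c in curves:
        data[c.sample_id or f"sample{curves.index(c)}"] = c.fluorescence
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_melt_tsv(path) -> dict[str, MeltCurve]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "temperature" not in df.columns:
        raise ParseError(f"{path}: missing 'temperature' column (line 1)")
    t = df["temperature"].to_numpy(dtype=float)
    out = {}
    for col in df.columns:
        if col == "temperature":
            continue
        try:
            out[col] = MeltCurve.from_arrays(t, df[col].to_numpy(dtype=float), col)
        except Exception as exc:
            raise ParseError(f"{path}: column {col!r}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: no sample columns found")
    return out


# ---------------------------------------------------------- assay config

def _seq_to_dict(seq: NucleotideSequence | None):
    return None if seq is None else {"id": seq.id, "bases": seq.bases}


def _seq_from_dict(d) -> NucleotideSequence | None:
    return None if d is None else NucleotideSequence(id=d["id"], bases=d["bases"])


def config_to_dict(config: AssayConfig) -> dict:
    return {
        "name": config.name,
        "primers": {
            "fwd": _seq_to_dict(config.primers.forward),
            "rev": _seq_to_dict(config.primers.reverse),
            "seq": [_seq_to_dict(s) for s in config.primers.sequencing],
        },
        "dispensations": [d.nucleotides for d in config.dispensations],
        "pair": None if config.pair is None else {
            "a": _seq_to_dict(config.pair.paralog_a),
            "b": _seq_to_dict(config.pair.paralog_b),
            "label_a": config.pair.label_a,
            "label_b": config.pair.label_b,
        },
        "region": _seq_to_dict(config.region),
        "windows": [list(w) for w in config.windows],
        "include_shift_in_estimation": config.include_shift_in_estimation,
        "max_mismatch": config.max_mismatch,
    }


def config_from_dict(d: Mapping) -> AssayConfig:
    try:
        pair = None
        if d.get("pair"):
            pair = ParalogPair(
                paralog_a=_seq_from_dict(d["pair"]["a"]),
                paralog_b=_seq_from_dict(d["pair"]["b"]),
                label_a=d["pair"].get("label_a", ""),
                label_b=d["pair"].get("label_b", ""),
            )
        primers = Primers(
            forward=_seq_from_dict(d["primers"].get("fwd")),
            reverse=_seq_from_dict(d["primers"].get("rev")),
            sequencing=tuple(_seq_from_dict(s)
                             for s in d["primers"].get("seq", [])),
        )
        return AssayConfig(
            name=d["name"],
            primers=primers,
            dispensations=tuple(DispensationOrder.from_string(x)
                                for x in d.get("dispensations", [])),
            pair=pair,
            region=_seq_from_dict(d.get("region")),
            windows=tuple((int(a), int(b)) for a, b in d.get("windows", [])),
            include_shift_in_estimation=bool(
                d.get("include_shift_in_estimation", False)),
            max_mismatch=int(d.get("max_mismatch", 3)),
        )
    except KeyError as exc:
        raise ParseError(f"assay config missing key {exc}") from exc


def read_config(path) -> AssayConfig:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return config_from_dict(d)


def write_config(path, config: AssayConfig) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=1)
        fh.write("\n")


def builtin_config(name: str) -> AssayConfig:
    """Load a packaged assay definition (``promoter`` or ``exon2``).

    These carry the published primer sequences and dispensation orders of
    the CDKN2A promoter and CDKN2A/CDKN2B exon-2 assays; template sequences
    are not shipped and must be attached from a user-supplied reference
    FASTA for sequence-level checks.
    """
    from importlib import resources
    ref = resources.files("paralogmeth.data").joinpath(f"{name}.json")
    if not ref.is_file():
        raise ParseError(f"no builtin assay named {name!r}")
    return config_from_dict(json.loads(ref.read_text()))


# -------------------------------------------------------------- results

def provenance(seed: int | None, config: AssayConfig | None = None) -> dict:
    prov = {"package": "paralogmeth", "version": __version__, "seed": seed}
    if config is not None:
        canon = json.dumps(config_to_dict(config), sort_keys=True)
        prov["config_sha256"] = hashlib.sha256(canon.encode()).hexdigest()[:16]
        prov["config_name"] = config.name
    return prov


def write_results(path, payload: Mapping, seed: int | None = None,
                  config: AssayConfig | None = None) -> None:
    out = dict(payload)
    out["provenance"] = provenance(seed, config)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
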