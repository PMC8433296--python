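"""Serialization: FASTA pools and primer libraries, JSON manifests.

Pool FASTA record ids encode ``<label>|<class>|<address>`` purely for
human inspection; the reader discards them, because retrieval must work
from sequence content alone. The manifest JSON bundles everything the
conventional-storage side of a hybrid system keeps: the storage method,
fragment geometry, per-stream index metadata, the primer assignment and
the tool-codec registry entries.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ToolRegistry
from .pool import Pool
from .primers import (
    Primer,
    PrimerPair,
    ROLE_FILE_F,
    ROLE_FILE_R,
)
from .storage import PoolManifest, StorePlan, StoreResult, StreamInfo


def write_pool_fasta(result: StoreResult, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=label, description="")
               for label, seq in result.fasta_records]
    SeqIO.write(records, str(path), "fasta")


def read_pool_fasta(path: str | Path) -> Pool:
    return Pool(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))


def write_primer_fasta(pairs: list[PrimerPair], path: str | Path,
                       universal: PrimerPair | None = None) -> None:
    records = []
    for pair in pairs:
        records.append(SeqRecord(Seq(pair.forward.sequence),
                                 id=f"pair{pair.id}_F", description=""))
        records.append(SeqRecord(Seq(pair.reverse.sequence),
                                 id=f"pair{pair.id}_R", description=""))
    if universal is not None:
        records.append(SeqRecord(Seq(universal.forward.sequence),
                                 id="universal_F", description=""))
        records.append(SeqRecord(Seq(universal.reverse.sequence),
                                 id="universal_R", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_primer_fasta(path: str | Path
                      ) -> tuple[list[PrimerPair], PrimerPair | None]:
    forwards: dict[str, str] = {}
    reverses: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, suffix = rec.id.rpartition("_")
        if suffix == "F":
            forwards[name] = str(rec.seq)
        elif suffix == "R":
            reverses[name] = str(rec.seq)
    pairs = []
    universal = None
    for name in forwards:
        if name not in reverses:
            continue
        if name == "universal":
            universal = PrimerPair(
                0, Primer(forwards[name], ROLE_FILE_F),
                Primer(reverses[name], ROLE_FILE_R)).as_universal()
        elif name.startswith("pair"):
            pid = int(name[4:])
            pairs.append(PrimerPair(pid,
                                    Primer(forwards[name], ROLE_FILE_F),
                                    Primer(reverses[name], ROLE_FILE_R)))
    pairs.sort(key=lambda p: p.id)
    return pairs, universal


def _pair_to_json(pair: PrimerPair) -> dict:
    return {"id": pair.id, "F": pair.forward.sequence,
            "R": pair.reverse.sequence}


def _pair_from_json(obj: dict, universal: bool = False) -> PrimerPair:
    pair = PrimerPair(obj["id"], Primer(obj["F"], ROLE_FILE_F),
                      Primer(obj["R"], ROLE_FILE_R))
    return pair.as_universal() if universal else pair


def _stream_to_json(info: StreamInfo) -> dict:
    return {"l_addr": info.l_addr, "nt_length": info.nt_length,
            "n_fragments": info.n_fragments,
            "pointer_nt": info.pointer_nt, "n_shared": info.n_shared,
            "clients": list(info.clients)}


def _stream_from_json(obj: dict) -> StreamInfo:
    return StreamInfo(obj["l_addr"], obj["nt_length"], obj["n_fragments"],
                      obj["pointer_nt"], obj["n_shared"],
                      tuple(obj["clients"]))


def write_manifest_json(manifest: PoolManifest, plan: StorePlan,
                        registry: ToolRegistry, path: str | Path) -> None:
    doc = {
        "method": manifest.method,
        "L_s": manifest.L_s,
        "L_p": manifest.L_p,
        "rs_len": manifest.rs_len,
        "codec": manifest.codec,
        "files": {str(fid): _stream_to_json(info)
                  for fid, info in manifest.files.items()},
        "tools": {str(fid): _stream_to_json(info)
                  for fid, info in manifest.tools.items()},
        "file_tool": {str(fid): tfid
                      for fid, tfid in manifest.file_tool.items()},
        "plan": {
            "file_primers": {str(fid): _pair_to_json(p)
                             for fid, p in plan.file_primers.items()},
            "tool_primers": {str(fid): _pair_to_json(p)
                             for fid, p in plan.tool_primers.items()},
            "universal": (_pair_to_json(plan.universal)
                          if plan.universal else None),
            "shared_counts": {str(k): v
                              for k, v in plan.shared_counts.items()},
        },
        "registry": {
            "by_fid": {str(fid): name
                       for fid, name in registry.codec_names().items()},
            "by_sha": registry.sha_names(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_manifest_json(path: str | Path
                       ) -> tuple[PoolManifest, StorePlan, ToolRegistry]:
    doc = json.loads(Path(path).read_text())
    manifest = PoolManifest(
        doc["method"], doc["L_s"], doc["L_p"], doc["rs_len"], doc["codec"],
        files={int(fid): _stream_from_json(o)
               for fid, o in doc["files"].items()},
        tools={int(fid): _stream_from_json(o)
               for fid, o in doc["tools"].items()},
        file_tool={int(fid): tfid
                   for fid, tfid in doc["file_tool"].items()},
    )
    pdoc = doc["plan"]
    plan = StorePlan(
        doc["method"],
        {int(fid): _pair_from_json(o)
         for fid, o in pdoc["file_primers"].items()},
        {int(fid): _pair_from_json(o)
         for fid, o in pdoc["tool_primers"].items()},
        (_pair_from_json(pdoc["universal"], universal=True)
         if pdoc["universal"] else None),
        {int(k): v for k, v in pdoc["shared_counts"].items()},
    )
    registry = ToolRegistry()
    for fid, name in doc["registry"]["by_fid"].items():
        registry.register(int(fid), name)
    for sha, name in doc["registry"]["by_sha"].items():
        registry.register_sha(sha, name)
    return manifest, plan, registry
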