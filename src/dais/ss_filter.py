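"""Secondary-structure gating of retained change features.

Change signals whose generator residues sit in regions without a defined
secondary structure (DSSP classes T, S and '-') are usually thermal noise
of loops and termini; this module demotes such features using a DSSP
annotation computed on the first Control frame.  DSSP output is consumed
as a file (classic columnar format, parsed with Bio.PDB); the artifact
does not run mkdssp itself, though `annotate_with_mkdssp` will call an
installed binary if one is present.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

from .change_scoring import STATUS_RETAINED, STATUS_UNSTRUCTURED, ChangeScore
from .errors import FormatError
from .trajectory_io import ResidueKey

logger = logging.getLogger(__name__)

DSSP_ALPHABET = frozenset("HGIEBTS-")
#: classes counted as "having a specific secondary structure"
STRUCTURED_CLASSES = frozenset("HGIEB")


@dataclass
class SSAnnotation:
    """Per-residue DSSP class map; unknown residues default to '-'."""

    classes: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in DSSP_ALPHABET}
        if bad:
            raise FormatError(f"unknown DSSP class(es): {sorted(bad)}")

    def get(self, key: ResidueKey) -> str:
        return self.classes.get(key, "-")

    def __len__(self) -> int:
        return len(self.classes)


def read_dssp(path: str) -> SSAnnotation:
    """Parse a classic DSSP output file into a per-residue class map."""
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, _keys = make_dssp_dict(path)
    except Exception as e:
        raise FormatError(f"cannot parse DSSP file {path}: {e}") from e
    classes: dict[ResidueKey, str] = {}
    for (chain, res_id), values in dssp_dict.items():
        ss = values[1] if values[1] != " " else "-"
        classes[(str(chain).strip() or "A", int(res_id[1]))] = ss
    return SSAnnotation(classes)


def write_dssp(ann: SSAnnotation, path: str, resnames: dict | None = None) -> None:
    """Write a minimal classic-format DSSP file (round-trips through
    read_dssp; used for synthetic fixtures)."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE unused",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, ((chain, resnum), ss) in enumerate(sorted(ann.classes.items())):
        aa = (resnames or {}).get((chain, resnum), "G")
        ss_out = " " if ss == "-" else ss
        line = f"{i + 1:5d}{resnum:5d} {chain:1.1s} {aa:1.1s}  {ss_out:1.1s}"
        line += " " * (34 - len(line))
        line += f"{0:4d}"
        for _ in range(4):  # four H-bond (relidx, energy) pairs
            line += f"{0:7d}" if len(line) == 38 else f"{0:6d}"
            line += f" {0.0:4.1f}"
        line += " " * (103 - len(line))
        line += f"{0.0:6.1f}{0.0:6.1f}"
        lines.append(line)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def annotate_with_mkdssp(pdb_path: str, out_path: str) -> SSAnnotation:
    """Run an installed mkdssp/dssp binary on a PDB file, if available."""
    exe = shutil.which("mkdssp") or shutil.which("dssp")
    if exe is None:
        raise FormatError("no mkdssp/dssp executable on PATH")
    subprocess.run([exe, pdb_path, out_path], check=True, capture_output=True)
    return read_dssp(out_path)


def filter_by_ss(
    scores: list[ChangeScore],
    ann: SSAnnotation,
    structured_classes: frozenset = STRUCTURED_CLASSES,
    min_fraction: float = 0.5,
) -> list[ChangeScore]:
    """Demote retained scores whose generator residues are mostly
    unstructured.

    A retained score stays retained iff at least ``min_fraction`` (closed
    bound) of its generator residues carry a class in
    ``structured_classes``.  Already-excluded scores are never promoted.
    Residues missing from the annotation count as '-' (with a warning).
    """
    missing = 0
    for s in scores:
        if s.status != STATUS_RETAINED:
            continue
        if not s.generators:
            continue
        cls = []
        for key in s.generators:
            if key not in ann.classes:
                missing += 1
            cls.append(ann.get(key))
        frac = sum(c in structured_classes for c in cls) / len(cls)
        if frac < min_fraction:
            s.status = STATUS_UNSTRUCTURED
    if missing:
        logger.warning(
            "%d generator residue(s) absent from DSSP annotation; treated as '-'",
            missing,
        )
    return scores
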