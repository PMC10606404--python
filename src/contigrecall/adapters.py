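"""Adapters binding external tools (or the built-in toys) to the phases.

External tools are declared as command templates, never hard-coded
paths; every invocation is logged with its full command line and exit
status.  Placeholders:

* aligner:   ``{target_fasta}``, ``{query_fasta}``, optional ``{out_paf}``
  (without it, stdout is captured as PAF)
* assembler: ``{reads_fasta}``, ``{out_dir}`` (FASTA contigs are collected
  from the output directory)
* assessor:  ``{fasta}``, ``{out_dir}`` (expects ``full_table.tsv`` in the
  output directory)
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from .io_formats import (
    SequenceRecord,
    parse_busco_full_table,
    parse_paf,
    read_fasta,
    write_fasta,
)
from .markers import MarkerCatalog, toy_marker_scan
from .synthetic import toy_align

logger = logging.getLogger(__name__)

# Plausible command lines for the assemblers the method is normally run
# with; users override them with site-specific templates.
BUILTIN_ASSEMBLER_TEMPLATES = {
    "hifiasm-like": "hifiasm -o {out_dir}/asm -t 4 {reads_fasta}",
    "hicanu-like": (
        "canu -p asm -d {out_dir} genomeSize=1m -pacbio-hifi {reads_fasta}"
    ),
}


class AdapterError(RuntimeError):
    """An external adapter command failed; diagnostics captured."""


def _run(command: str) -> subprocess.CompletedProcess:
    logger.info("adapter command: %s", command)
    proc = subprocess.run(
        command, shell=True, capture_output=True, text=True
    )
    logger.info("adapter exit status: %d", proc.returncode)
    if proc.returncode != 0:
        raise AdapterError(
            f"command failed ({proc.returncode}): {command}\n"
            f"stdout: {proc.stdout[-2000:]}\nstderr: {proc.stderr[-2000:]}"
        )
    return proc


class ExternalAligner:
    """Run an external aligner (e.g. minimap2 -x asm5) via its template."""

    def __init__(self, template: str, workdir: str | Path | None = None):
        self.template = template
        self.workdir = Path(workdir) if workdir else None

    def __call__(
        self,
        queries: Sequence[SequenceRecord],
        targets: Sequence[SequenceRecord],
    ):
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            q_path, t_path = tmp / "query.fasta", tmp / "target.fasta"
            write_fasta(queries, q_path)
            write_fasta(targets, t_path)
            out_paf = tmp / "out.paf"
            command = self.template.format(
                query_fasta=q_path, target_fasta=t_path, out_paf=out_paf
            )
            proc = _run(command)
            if "{out_paf}" not in self.template:
                out_paf.write_text(proc.stdout)
            return parse_paf(out_paf)


class ExternalAssembler:
    def __init__(self, template: str, workdir: str | Path | None = None):
        self.template = BUILTIN_ASSEMBLER_TEMPLATES.get(template, template)
        self.workdir = Path(workdir) if workdir else None

    def __call__(self, reads: Sequence[SequenceRecord]):
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            reads_path = tmp / "reads.fasta"
            out_dir = tmp / "asm"
            out_dir.mkdir()
            write_fasta(reads, reads_path)
            _run(self.template.format(reads_fasta=reads_path, out_dir=out_dir))
            contigs: list[SequenceRecord] = []
            for fasta in sorted(out_dir.glob("**/*.fa")) + sorted(
                out_dir.glob("**/*.fasta")
            ):
                contigs.extend(read_fasta(fasta))
            if not contigs:
                raise AdapterError(
                    f"assembler produced no FASTA output under {out_dir}"
                )
            return contigs


class ExternalAssessor:
    def __init__(self, template: str, workdir: str | Path | None = None):
        self.template = template
        self.workdir = Path(workdir) if workdir else None

    def __call__(self, records: Sequence[SequenceRecord]):
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            fasta = tmp / "assembly.fasta"
            out_dir = tmp / "assessor"
            out_dir.mkdir()
            write_fasta(records, fasta)
            _run(self.template.format(fasta=fasta, out_dir=out_dir))
            table = out_dir / "full_table.tsv"
            if not table.exists():
                raise AdapterError(f"assessor produced no {table}")
            return parse_busco_full_table(table)


def make_adapters(config, catalog: MarkerCatalog, workdir: str | Path | None = None):
    """(assessor, aligner, assembler) per the config's adapter specs.

    The string ``"toy"`` selects the built-ins; anything else is treated
    as an external command template (or a built-in template name for the
    assembler).
    """
    if config.assessor == "toy":
        assessor = lambda recs: toy_marker_scan(recs, catalog)  # noqa: E731
    else:
        assessor = ExternalAssessor(config.assessor, workdir)
    if config.aligner == "toy":
        aligner = toy_align
    else:
        aligner = ExternalAligner(config.aligner, workdir)
    if config.assembler == "toy":
        assembler = None  # fill_assembly falls back to toy_assemble
    else:
        assembler = ExternalAssembler(config.assembler, workdir)
    return assessor, aligner, assembler
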