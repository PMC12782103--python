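"""Assemble analysis outputs into an ordered, sectioned markdown document.

Elements (headings, free text, figures, tables) carry explicit positions
and can be reordered by permutation.  Rendering produces one
self-contained markdown file with relative image links and inlined pipe
tables, plus a provenance block (config hash, seed, tool version) so a
report is a pure function of its elements and inputs.  Conversion to a
word-processor format is delegated to pandoc when available on PATH and
silently degrades to markdown-only otherwise.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ReportElement", "Report"]

ELEMENT_KINDS = ("heading", "text", "figure", "table")


@dataclass
class ReportElement:
    kind: str
    content: str  # markdown text, or a path for figure/table elements
    position: int

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")


@dataclass
class Report:
    title: str
    elements: list[ReportElement] = field(default_factory=list)
    config_hash: str = ""
    seed: int | None = None
    tool_version: str = ""

    def add_element(self, kind: str, content: str) -> ReportElement:
        el = ReportElement(kind=kind, content=content, position=len(self.elements))
        self.elements.append(el)
        return el

    def reorder(self, permutation: list[int]) -> None:
        """Apply a permutation of current positions; content unchanged."""
        if sorted(permutation) != list(range(len(self.elements))):
            raise ValueError(
                f"permutation must be a bijection on 0..{len(self.elements) - 1}"
            )
        self.elements = [self.elements[i] for i in permutation]
        for pos, el in enumerate(self.elements):
            el.position = pos

    # -- rendering --------------------------------------------------------
    def _provenance(self) -> str:
        prov = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "tool_version": self.tool_version,
        }
        return "```provenance\n" + json.dumps(prov, indent=2) + "\n```\n"

    def render(self, out_path: str | Path, to_docx: bool = False) -> Path:
        """Write the markdown document; idempotent (no timestamps)."""
        out_path = Path(out_path)
        parts = [f"# {self.title}\n", self._provenance()]
        for el in sorted(self.elements, key=lambda e: e.position):
            if el.kind == "heading":
                parts.append(f"## {el.content}\n")
            elif el.kind == "text":
                parts.append(el.content.rstrip() + "\n")
            elif el.kind == "figure":
                fig = Path(el.content)
                if not fig.exists():
                    raise FileNotFoundError(f"figure not found: {fig}")
                rel = Path(os.path.relpath(fig, out_path.parent))
                parts.append(f"![{fig.stem}]({rel})\n")
            elif el.kind == "table":
                tab = Path(el.content)
                if not tab.exists():
                    raise FileNotFoundError(f"table not found: {tab}")
                frame = pd.read_csv(tab)
                parts.append(frame.to_markdown(index=False, floatfmt=".4g") + "\n")
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text("\n".join(parts))
        if to_docx:
            self._convert_docx(out_path)
        return out_path

    @staticmethod
    def _convert_docx(md_path: Path) -> Path | None:
        pandoc = shutil.which("pandoc")
        if pandoc is None:
            warnings.warn(
                "no document converter on PATH; keeping markdown only", stacklevel=2
            )
            return None
        docx = md_path.with_suffix(".docx")
        try:
            subprocess.run(
                [pandoc, str(md_path), "-o", str(docx)],
                check=True,
                capture_output=True,
                cwd=md_path.parent,
            )
        except subprocess.CalledProcessError as exc:
            warnings.warn(f"document conversion failed: {exc}", stacklevel=2)
            return None
        return docx


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping for provenance."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
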