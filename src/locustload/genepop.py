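"""GENEPOP flat-file reader and writer.

The GENEPOP text format holds diploid genotypes: a free-text title
line, one locus name per line (or all loci comma-separated on one
line), then one ``Pop`` block per population with lines of the form
``individual_name ,  010012 020020 ...``.  Alleles are coded with a
fixed number of digits (2 or 3); ``00``/``000`` codes a missing allele.
The digit width is auto-detected from the genotype token length.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .popgen import GenotypeTable

__all__ = ["read_genepop", "write_genepop"]


def write_genepop(
    table: GenotypeTable, path, title: str = "locustload genotypes", digits: int = 3
) -> None:
    """Write a :class:`GenotypeTable` in the 2- or 3-digit GENEPOP dialect."""
    if digits not in (2, 3):
        raise ValueError("GENEPOP allele codes use 2 or 3 digits")
    limit = 10**digits
    lines = [title]
    lines.extend(table.loci)
    for pop, arr in table.populations.items():
        lines.append("Pop")
        names = table.individual_names.get(
            pop, [f"{pop}_{i + 1}" for i in range(arr.shape[0])]
        )
        for name, ind in zip(names, arr):
            if (ind >= limit).any():
                raise ValueError(
                    f"allele code >= {limit} cannot be written with {digits} digits"
                )
            geno = " ".join(f"{a:0{digits}d}{b:0{digits}d}" for a, b in ind)
            lines.append(f"{name} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_genepop(path) -> GenotypeTable:
    """Parse a GENEPOP file; population labels default to the last
    individual name of each block (the format's convention), falling
    back to ``pop1``, ``pop2``, ... on duplicates."""
    raw = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in raw if ln]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GENEPOP file (too short)")

    body = lines[1:]  # drop title
    try:
        first_pop = next(i for i, ln in enumerate(body) if ln.lower() == "pop")
    except StopIteration:
        raise ValueError(f"{path}: no 'Pop' separator found") from None

    loci: list = []
    for ln in body[:first_pop]:
        loci.extend(x.strip() for x in ln.split(",") if x.strip())
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'Pop'")

    blocks: list = [[]]
    for ln in body[first_pop:]:
        if ln.lower() == "pop":
            if blocks[-1]:
                blocks.append([])
        else:
            blocks[-1].append(ln)
    blocks = [b for b in blocks if b]

    digits = None
    populations: dict = {}
    names_by_pop: dict = {}
    labels: list = []
    for b_i, block in enumerate(blocks):
        inds = []
        names = []
        for ln in block:
            if "," not in ln:
                raise ValueError(f"{path}: genotype line missing ',': {ln!r}")
            name, geno_part = ln.split(",", 1)
            tokens = geno_part.split()
            if len(tokens) != len(loci):
                raise ValueError(
                    f"{path}: individual {name.strip()!r} has {len(tokens)} "
                    f"genotypes for {len(loci)} loci"
                )
            row = []
            for tok in tokens:
                if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                    raise ValueError(f"{path}: malformed genotype token {tok!r}")
                d = len(tok) // 2
                if digits is None:
                    digits = d
                elif digits != d:
                    raise ValueError(f"{path}: mixed 2- and 3-digit allele codes")
                row.append((int(tok[:d]), int(tok[d:])))
            inds.append(row)
            names.append(name.strip())
        label = f"pop{b_i + 1}"
        if names:
            m = re.fullmatch(r"(.+?)[_-]\d+", names[0])
            if m and all(n.startswith(m.group(1)) for n in names):
                label = m.group(1)  # shared stem like "England_1", "England_2"
            else:
                label = names[-1]  # the format's usual block label
        if label in populations:
            label = f"pop{b_i + 1}"
        labels.append(label)
        populations[label] = np.array(inds, dtype=np.int64).reshape(
            len(inds), len(loci), 2
        )
        names_by_pop[label] = names

    return GenotypeTable(
        loci=loci, populations=populations, individual_names=names_by_pop
    )
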