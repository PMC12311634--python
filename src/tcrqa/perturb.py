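"""Input-feature perturbation operators for diversifying model pools.

These operate on MSAs (A3M conventions: lowercase = insertion columns,
which are ignored when comparing row lengths) and on template structures.
They emulate the knobs a structure-prediction pipeline exposes to increase
the conformational diversity of its candidate models: random or column-wise
substitution of MSA residues, masking (subsampling) of MSA rows, and
Gaussian noise on template coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import StructureModel

__all__ = [
    "MSAData",
    "PipelinePreset",
    "PIPELINE_PRESETS",
    "read_a3m",
    "write_a3m",
    "mutate_msa_random",
    "mutate_msa_columnwise",
    "mask_msa_rows",
    "noise_template_coords",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MASK = "X"


@dataclass(frozen=True)
class PipelinePreset:
    """One candidate-generation configuration of the modeling pipeline."""
    name: str
    template_policy: str
    msa_mask_fraction: float
    msa_mutation_rate: float
    candidates_per_af_model: int
    n_af_models: int = 5
    max_recycles: int = 3

    @property
    def total_candidates(self) -> int:
        return self.candidates_per_af_model * self.n_af_models


#: the four pool-diversification configurations; together they yield the
#: 750-candidate pool produced per input complex
PIPELINE_PRESETS = (
    PipelinePreset("unrestricted-templates", "unrestricted", 0.0, 0.0, 30),
    PipelinePreset("pmhc-templates-heavy-perturb", "pmhc-only", 0.60, 0.60, 30),
    PipelinePreset("pmhc-templates-light-perturb", "pmhc-only", 0.20, 0.20, 30),
    PipelinePreset("dated-templates-mild-perturb", "date-capped-sim90", 0.15, 0.15, 60),
)


def _match_length(row: str) -> int:
    """Length of a row after dropping lowercase insertion columns."""
    return sum(1 for c in row if not c.islower())


@dataclass
class MSAData:
    query: str
    rows: list = field(default_factory=list)
    names: list = field(default_factory=list)

    def __post_init__(self):
        q = _match_length(self.query)
        for i, row in enumerate(self.rows):
            if _match_length(row) != q:
                raise ValueError(
                    f"row {i} has {_match_length(row)} match columns, query has {q}")
        if not self.names:
            self.names = [f"seq{i}" for i in range(len(self.rows))]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_a3m(path) -> MSAData:
    names, seqs = [], []
    with open(str(path)) as fh:
        name, chunks = None, []
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    names.append(name)
                    seqs.append("".join(chunks))
                name, chunks = line[1:], []
            else:
                chunks.append(line)
        if name is not None:
            names.append(name)
            seqs.append("".join(chunks))
    if not seqs:
        raise ValueError(f"{path}: empty A3M")
    return MSAData(query=seqs[0], rows=seqs[1:], names=names[1:])


def write_a3m(msa: MSAData, path, query_name="query") -> None:
    with open(str(path), "w") as fh:
        fh.write(f">{query_name}\n{msa.query}\n")
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


def mutate_msa_random(msa: MSAData, rate: float, seed: int = 0) -> MSAData:
    """Substitute each non-gap homolog residue with probability ``rate``.

    Substitutions draw uniformly from the 19 other standard amino acids;
    the query row is never touched.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    new_rows = []
    for row in msa.rows:
        chars = list(row)
        for i, c in enumerate(chars):
            if c == GAP or c.islower():
                continue
            if rate >= 1.0 or rng.uniform() < rate:
                choices = [a for a in AA20 if a != c.upper()]
                chars[i] = choices[int(rng.integers(len(choices)))]
        new_rows.append("".join(chars))
    return MSAData(query=msa.query, rows=new_rows, names=list(msa.names))


def mutate_msa_columnwise(msa: MSAData, rate: float, seed: int = 0) -> MSAData:
    """Replace whole match columns: each selected column (probability ``rate``)
    gets one random amino acid written into every non-gap homolog entry."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # map match-column index -> per-row string position (rows may differ by
    # lowercase insertions)
    def match_positions(row):
        return [i for i, c in enumerate(row) if not c.islower()]

    n_cols = _match_length(msa.query)
    selected = [rate >= 1.0 or rng.uniform() < rate for _ in range(n_cols)]
    col_aa = [AA20[int(rng.integers(20))] for _ in range(n_cols)]
    new_rows = []
    for row in msa.rows:
        chars = list(row)
        for col, pos in enumerate(match_positions(row)):
            if selected[col] and chars[pos] != GAP:
                chars[pos] = col_aa[col]
        new_rows.append("".join(chars))
    return MSAData(query=msa.query, rows=new_rows, names=list(msa.names))


def mask_msa_rows(msa: MSAData, fraction: float, seed: int = 0,
                  replace_with_mask: bool = False) -> MSAData:
    """Remove (default) or mask floor(fraction * n_rows) homolog rows.

    The query row is always retained. With ``replace_with_mask`` the selected
    rows stay in place with every match-column residue replaced by 'X'.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_drop = int(np.floor(fraction * msa.n_rows))
    drop = set(rng.choice(msa.n_rows, size=n_drop, replace=False)) if n_drop else set()
    rows, names = [], []
    for i, (row, name) in enumerate(zip(msa.rows, msa.names)):
        if i in drop:
            if replace_with_mask:
                rows.append("".join(MASK if (not c.islower() and c != GAP) else c
                                    for c in row))
                names.append(name)
            continue
        rows.append(row)
        names.append(name)
    return MSAData(query=msa.query, rows=rows, names=names)


def noise_template_coords(template: StructureModel, sigma: float,
                          seed: int = 0) -> StructureModel:
    """Add i.i.d. zero-mean Gaussian offsets (SD ``sigma``) to every atom coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = template.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for res in out.residues:
        for name in res.coords:
            res.coords[name] = res.coords[name] + rng.normal(0.0, sigma, size=3)
    return out
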