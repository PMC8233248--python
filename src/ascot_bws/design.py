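"""Experimental plan for the profile-case best-worst experiment.

The full factorial over 8 four-level factors (7 instrument domains plus a
blocking factor) has 4^8 scenarios; an orthogonal main-effects plan (OMEP)
reduces it to 32.  We construct an OA(32, 8, 4, 2) -- 32 runs, 8 four-level
columns, strength 2 -- by collapsing pairs of columns of the two-level
Hadamard-derived array OA(32, 31, 2, 2): the 31 binary columns correspond to
the nonzero vectors of GF(2)^5, and any 8 pairwise disjoint "closed triples"
{a, b, a XOR b} (lines of PG(4,2)) yield 8 four-level columns that are
mutually strength-2 orthogonal.  A partial spread of 8 disjoint lines always
exists (the maximum is 9); a seeded backtracking search finds one, and a
vetted fixture array ships with the package as a fallback.

The 8th column is used as the blocking factor: its four symbols split the 32
scenarios into 4 blocks of 8 tasks, and each respondent sees one block.
Strength 2 against the blocking column guarantees that within every block
each domain shows each of its four levels exactly twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .instrument import AttributeLevel, InstrumentSpec, N_LEVELS, default_instrument

N_RUNS = 32
N_FACTORS = 8
N_BLOCKS = 4
TASKS_PER_BLOCK = 8


class DesignError(ValueError):
    """Construction or verification failure of the experimental plan."""


@dataclass(frozen=True)
class DesignPlan:
    """A 32 x 8 strength-2 orthogonal array with a designated blocking column.

    ``matrix`` entries are symbols in {0,1,2,3}; the first 7 columns map
    one-to-one onto the instrument domains (instrument order) and the last
    column is the blocking factor.  Symbol ``s`` renders as outcome level
    ``s + 1``.
    """

    matrix: np.ndarray
    block_column: int = N_FACTORS - 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2:
            raise DesignError(f"design matrix must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def domain_columns(self) -> list[int]:
        return [c for c in range(self.matrix.shape[1]) if c != self.block_column]

    def block_of_row(self, row: int) -> int:
        return int(self.matrix[row, self.block_column])


@dataclass(frozen=True)
class ChoiceTask:
    """One choice set: one item per domain, plus its on-screen ordering.

    ``items`` follow instrument domain order; ``display_order`` lists domain
    indices top-to-bottom as shown to the respondent, so the display position
    (1 = uppermost) of the item for domain ``d`` is
    ``display_order.index(d) + 1``.
    """

    task_id: int
    block: int
    items: tuple[AttributeLevel, ...]
    display_order: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.items)
        if sorted(self.display_order) != list(range(n)):
            raise DesignError(
                f"display_order must be a permutation of 0..{n - 1}, "
                f"got {self.display_order}"
            )

    def position_of(self, domain_index: int) -> int:
        """1-based display position of the given domain's item."""
        return self.display_order.index(domain_index) + 1


@dataclass(frozen=True)
class VerificationReport:
    passed: bool
    balance_violations: list
    pair_violations: list
    pair_counts: dict

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


# ---------------------------------------------------------------------------
# construction

def _all_lines() -> list[tuple[int, int, int]]:
    """All 155 lines {a, b, a^b} of PG(4,2), points encoded as ints 1..31."""
    lines = set()
    for a in range(1, 32):
        for b in range(a + 1, 32):
            c = a ^ b
            lines.add(tuple(sorted((a, b, c))))
    return sorted(lines)


def _find_partial_spread(rng: np.random.Generator, size: int = N_FACTORS,
                         max_nodes: int = 200_000) -> list[tuple[int, int, int]]:
    """Seeded depth-first search for ``size`` pairwise disjoint lines."""
    lines = _all_lines()
    order = rng.permutation(len(lines))
    lines = [lines[i] for i in order]
    chosen: list[tuple[int, int, int]] = []
    used = 0  # bitmask of covered points
    nodes = 0

    def dfs(start: int) -> bool:
        nonlocal used, nodes
        if len(chosen) == size:
            return True
        for i in range(start, len(lines)):
            nodes += 1
            if nodes > max_nodes:
                return False
            mask = 0
            for p in lines[i]:
                mask |= 1 << p
            if used & mask:
                continue
            chosen.append(lines[i])
            used |= mask
            if dfs(i + 1):
                return True
            chosen.pop()
            used &= ~mask
        return False

    if not dfs(0):
        raise DesignError(
            "no disjoint-line partition found within the search budget; "
            "use load_fixture_design() instead"
        )
    return chosen


def _array_from_spread(spread: list[tuple[int, int, int]]) -> np.ndarray:
    """Collapse each line's first two binary columns into one 4-level column."""
    runs = np.arange(N_RUNS)

    def parity(vec: int) -> np.ndarray:
        # <vec, x> over GF(2) for every run x
        bits = runs & vec
        out = np.zeros(N_RUNS, dtype=int)
        while bits.any():
            out ^= bits & 1
            bits >>= 1
        return out

    cols = []
    for a, b, _ in spread:
        cols.append(2 * parity(a) + parity(b))
    return np.column_stack(cols)


def build_design(seed: int = 0) -> DesignPlan:
    """Construct an OA(32, 8, 4, 2) plan; deterministic for a fixed seed.

    The result always satisfies :func:`verify_design`; construction failure
    raises rather than returning an unverified array.
    """
    rng = np.random.default_rng(seed)
    spread = _find_partial_spread(rng)
    matrix = _array_from_spread(spread)
    plan = DesignPlan(
        matrix=matrix,
        metadata={
            "method": "hadamard-collapse",
            "seed": int(seed),
            "lines": [list(t) for t in spread],
            "symbol_to_level": "level = symbol + 1",
        },
    )
    report = verify_design(plan)
    if not report.passed:  # pragma: no cover - construction is provably valid
        raise DesignError(f"constructed array failed verification: {report}")
    return plan


def load_fixture_design() -> DesignPlan:
    """Load the vetted OA(32, 8, 4, 2) table shipped with the package."""
    text = (
        resources.files("ascot_bws").joinpath("data/oa32_8_4_2.csv").read_text("utf-8")
    )
    rows = [
        [int(v) for v in line.split(",")]
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    return DesignPlan(
        matrix=np.array(rows, dtype=int),
        metadata={"method": "fixture", "symbol_to_level": "level = symbol + 1"},
    )


# ---------------------------------------------------------------------------
# verification

def verify_design(plan: DesignPlan) -> VerificationReport:
    """Exhaustive balance and strength-2 check of every column pair.

    A 4-level column is balanced when each symbol appears n_runs/4 times; a
    column pair is strength-2 orthogonal when each of the 16 ordered symbol
    pairs appears n_runs/16 times.  Counting is exhaustive, not sampled.
    """
    m = plan.matrix
    if m.ndim != 2:
        raise DesignError("design matrix must be rectangular")
    if not np.isin(m, np.arange(N_LEVELS)).all():
        raise DesignError("matrix entries must be symbols in {0,1,2,3}")
    n_runs, n_cols = m.shape
    if n_runs % (N_LEVELS * N_LEVELS) != 0:
        raise DesignError(
            f"run count {n_runs} is not a multiple of {N_LEVELS * N_LEVELS}"
        )
    per_symbol = n_runs // N_LEVELS
    per_pair = n_runs // (N_LEVELS * N_LEVELS)

    balance_violations = []
    for c in range(n_cols):
        counts = np.bincount(m[:, c], minlength=N_LEVELS)
        if not (counts == per_symbol).all():
            balance_violations.append((c, counts.tolist()))

    pair_violations = []
    pair_counts = {}
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            table = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
            np.add.at(table, (m[:, i], m[:, j]), 1)
            pair_counts[(i, j)] = table
            if not (table == per_pair).all():
                pair_violations.append((i, j, table.tolist()))

    return VerificationReport(
        passed=not balance_violations and not pair_violations,
        balance_violations=balance_violations,
        pair_violations=pair_violations,
        pair_counts=pair_counts,
    )


# ---------------------------------------------------------------------------
# blocking and display randomisation

def block_design(plan: DesignPlan, spec: InstrumentSpec | None = None
                 ) -> list[list[ChoiceTask]]:
    """Partition the 32 scenarios into 4 blocks of 8 tasks.

    Rows are grouped by the blocking column's symbol; the blocking column is
    not rendered as an item.  Tasks carry the identity display order until
    :func:`randomize_display` is applied.
    """
    spec = spec or default_instrument()
    report = verify_design(plan)
    if not report.passed:
        raise DesignError("plan failed verification; refusing to block it")
    block_col = plan.matrix[:, plan.block_column]
    counts = np.bincount(block_col, minlength=N_BLOCKS)
    if not (counts == TASKS_PER_BLOCK).all():
        raise DesignError(f"blocking column not 4-way balanced: {counts.tolist()}")
    domain_cols = plan.domain_columns
    if len(domain_cols) != spec.n_domains:
        raise DesignError(
            f"plan has {len(domain_cols)} domain columns for "
            f"{spec.n_domains} instrument domains"
        )
    identity = tuple(range(spec.n_domains))
    blocks: list[list[ChoiceTask]] = [[] for _ in range(N_BLOCKS)]
    for row in range(plan.n_runs):
        items = tuple(
            AttributeLevel(spec.domains[d].code, int(plan.matrix[row, col]) + 1)
            for d, col in enumerate(domain_cols)
        )
        b = int(block_col[row])
        blocks[b].append(
            ChoiceTask(task_id=row, block=b, items=items, display_order=identity)
        )
    return blocks


def randomize_display(tasks: list[ChoiceTask], respondent_seed: int
                      ) -> list[ChoiceTask]:
    """Apply one per-respondent display permutation to all of their tasks.

    The survey randomised the on-screen ordering of the domain statements
    across individuals (constant within a respondent) to keep positioning
    effects estimable.  Deterministic for a fixed ``respondent_seed``.
    """
    if not tasks:
        raise DesignError("tasks must be non-empty")
    n = len(tasks[0].items)
    rng = np.random.default_rng(respondent_seed)
    perm = tuple(int(x) for x in rng.permutation(n))
    return [replace(t, display_order=perm) for t in tasks]


# ---------------------------------------------------------------------------
# on-disk format

def write_design_csv(plan: DesignPlan, path: str | Path,
                     spec: InstrumentSpec | None = None) -> None:
    """Design CSV: one scenario per row, integer levels 1-4 plus block 0-3.

    Header comments record seed and construction method.
    """
    spec = spec or default_instrument()
    lines = [
        f"# method={plan.metadata.get('method', 'unknown')}",
        f"# seed={plan.metadata.get('seed', 'n/a')}",
        "# symbol_to_level: level = symbol + 1 (domain columns); block column raw 0-3",
        ",".join(list(spec.domain_codes) + ["block"]),
    ]
    for row in range(plan.n_runs):
        levels = [str(int(plan.matrix[row, c]) + 1) for c in plan.domain_columns]
        lines.append(",".join(levels + [str(plan.block_of_row(row))]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_design_csv(path: str | Path, spec: InstrumentSpec | None = None
                    ) -> DesignPlan:
    spec = spec or default_instrument()
    metadata: dict = {}
    rows = []
    header: list[str] | None = None
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                metadata[key.strip()] = val.strip()
            continue
        if header is None:
            header = line.split(",")
            expected = list(spec.domain_codes) + ["block"]
            if header != expected:
                raise DesignError(
                    f"line {lineno}: design header {header} != expected {expected}"
                )
            continue
        try:
            vals = [int(v) for v in line.split(",")]
        except ValueError:
            raise DesignError(f"line {lineno}: non-integer design entry") from None
        if len(vals) != spec.n_domains + 1:
            raise DesignError(f"line {lineno}: expected {spec.n_domains + 1} columns")
        *levels, block = vals
        for code, lev in zip(spec.domain_codes, levels):
            if lev not in (1, 2, 3, 4):
                raise DesignError(f"line {lineno}: level {lev} out of range for {code}")
        if block not in range(N_BLOCKS):
            raise DesignError(f"line {lineno}: block {block} out of range")
        rows.append([lev - 1 for lev in levels] + [block])
    if header is None:
        raise DesignError("design file has no header row")
    return DesignPlan(matrix=np.array(rows, dtype=int), metadata=metadata)
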