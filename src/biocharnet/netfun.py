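"""Spearman co-occurrence networks and rule-based function annotation.

Co-occurrence networks connect genera whose per-sample relative abundances
are rank-correlated beyond a threshold (|rho| >= 0.9 by default).  Function
annotation maps taxonomy lineages to ecological functions through a
FAPROTAX-style rule file (simplified dialect: one rule per line,
``pattern<TAB>function1,function2``, pattern matched as a substring of any
rank token of the lineage); per-sample function abundance is the summed
relative abundance of the OTUs carrying the function, optionally restricted
to one module's OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import OTUTable


class RuleParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# co-occurrence network

def spearman_network(
    genus_matrix: pd.DataFrame,
    threshold: float = 0.9,
    samples: list[str] | None = None,
) -> nx.Graph:
    """Spearman co-occurrence graph on a genus x sample abundance matrix.

    Edges connect genus pairs with |rho| >= ``threshold`` within the chosen
    samples; isolated genera remain as nodes.  Constant genera are excluded
    with a warning (rho undefined).
    """
    m = genus_matrix if samples is None else genus_matrix[samples]
    if m.shape[1] < 4:
        raise ValueError("need at least 4 samples for a co-occurrence network")
    const = m.index[m.std(axis=1) == 0]
    if len(const):
        warnings.warn(
            f"excluding {len(const)} constant genus vector(s): "
            f"{list(const)[:5]}", stacklevel=2,
        )
        m = m.drop(index=const)
    g = nx.Graph()
    g.add_nodes_from(m.index)
    if m.shape[0] >= 2:
        rho = stats.spearmanr(m.to_numpy(), axis=1).statistic
        if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 variables
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        names = list(m.index)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(rho[i, j]) >= threshold:
                    g.add_edge(names[i], names[j], rho=float(rho[i, j]))
    return g


def network_stats(g: nx.Graph) -> dict:
    """Node/edge counts, density 2E/(N(N-1)) and mean degree."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    mean_degree = 0.0 if n == 0 else 2.0 * e / n
    return {"nodes": n, "edges": e, "density": density, "mean_degree": mean_degree}


def genus_abundance(table: OTUTable, otus: list[str] | None = None) -> pd.DataFrame:
    """Genus x sample relative-abundance matrix, optionally from a subset of OTUs."""
    rel = table.relative_abundance()
    genus = table.rank_labels("genus")
    if otus is not None:
        rel = rel.loc[otus]
        genus = genus.loc[otus]
    return rel.groupby(genus).sum()


# ---------------------------------------------------------------------------
# function annotation

@dataclass
class FunctionRuleSet:
    """Ordered taxonomy-pattern -> function-set rules."""

    rules: list[tuple[str, tuple[str, ...]]]

    @property
    def functions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, funcs in self.rules:
            for f in funcs:
                seen.setdefault(f, None)
        return list(seen)


def load_rules(path=None) -> FunctionRuleSet:
    """Parse a rule file; ``None`` loads the bundled miniature rule set."""
    if path is None:
        src = resources.files("biocharnet").joinpath("data/function_rules.tsv")
        lines = src.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    rules = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise RuleParseError(f"malformed rule at line {ln}: {line!r}")
        funcs = tuple(f.strip() for f in parts[1].split(",") if f.strip())
        if len(set(funcs)) != len(funcs):
            raise RuleParseError(f"duplicate function names at line {ln}")
        rules.append((parts[0].strip(), funcs))
    return FunctionRuleSet(rules)


def annotate_functions(
    taxonomy: pd.Series, rules: FunctionRuleSet
) -> dict[str, set[str]]:
    """OTU -> set of functions whose pattern matches any rank of the lineage."""
    out: dict[str, set[str]] = {}
    for otu, lineage in taxonomy.items():
        tokens = [tok.strip() for tok in str(lineage).split(";")]
        funcs: set[str] = set()
        for pattern, fs in rules.rules:
            if any(pattern in tok for tok in tokens):
                funcs.update(fs)
        out[otu] = funcs
    return out


def function_abundance(
    table: OTUTable,
    assignments: dict[str, set[str]],
    restrict_to: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample relative abundance of each function.

    A function's abundance in a sample is the summed relative abundance of
    the OTUs carrying it (an OTU with several functions contributes its full
    abundance to each — the FAPROTAX convention).  ``restrict_to`` limits
    the OTUs considered (e.g. one module's members); abundances stay
    relative to the whole community.
    """
    rel = table.relative_abundance()
    if restrict_to is not None:
        missing = set(restrict_to) - set(rel.index)
        if missing:
            raise KeyError(f"unknown OTU(s) in restriction: {sorted(missing)[:5]}")
        rel = rel.loc[list(restrict_to)]
    functions = sorted({f for fs in assignments.values() for f in fs})
    out = pd.DataFrame(0.0, index=functions, columns=rel.columns)
    for otu in rel.index:
        for f in assignments.get(otu, ()):
            out.loc[f] += rel.loc[otu]
    return out
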