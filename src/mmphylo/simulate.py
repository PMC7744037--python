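"""Forward simulation under a Markov-modulated model on a tree.

Each site evolves independently: a root compound state is drawn from the
stationary distribution Pi_Lambda, then a Gillespie (competing
exponentials) path is simulated down every branch with the rates of the
compound generator. The full event history — every within-model
substitution and every between-model switch — is recorded, so the hidden
model path that inference and reconstruction try to recover is available
as ground truth.

Randomness uses one counter-based Philox stream per site keyed by
(master seed, site index), so simulating more sites never reshuffles the
sites already generated.

With ASRV each site first draws its gamma category, whose rate rescales
branch time for the whole compound process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .mmm import CompoundModel, MMMSpec, compose_compound_generator, spec_to_dict
from .phylo import Alignment, Tree, random_tree, write_alignment, write_tree


@dataclass
class Event:
    """A single jump of the compound chain on a branch."""

    time: float  # distance from the parent end of the branch
    from_state: int  # compound index before the jump
    to_state: int

    def is_model_switch(self, n_states: int) -> bool:
        return self.from_state // n_states != self.to_state // n_states


@dataclass
class SimulationResult:
    """Alignment plus the generating hidden truth."""

    alignment: Alignment
    node_states: np.ndarray  # (n_nodes, n_sites) compound indices
    events: dict  # (child_node, site) -> list[Event]
    categories: np.ndarray | None  # per-site ASRV category index
    seed: int
    tree: Tree
    compound: CompoundModel

    def model_states(self) -> np.ndarray:
        """(n_nodes, n_sites) hidden model-category indices."""
        return self.node_states // self.compound.n_states

    def char_states(self) -> np.ndarray:
        return self.node_states % self.compound.n_states


def _site_rng(seed: int, site: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, site]))


class _JumpTables:
    """Per-state exit rates and cumulative jump distributions of a generator.

    Cumulative rows are plain Python lists: bisection on them is several
    times faster than numpy searchsorted at these tiny sizes, and the
    simulator's inner loop is pure scalar work.
    """

    def __init__(self, lam: np.ndarray):
        self.exit = [float(-lam[i, i]) for i in range(lam.shape[0])]
        jump = lam.copy()
        np.fill_diagonal(jump, 0.0)
        self.cum = [row.cumsum().tolist() for row in jump]


def _gillespie(rng, tables: _JumpTables, state: int, t_total: float):
    """Simulate jumps of a CTMC over ``t_total`` via competing exponentials."""
    from bisect import bisect_left

    events = []
    t = 0.0
    while True:
        exit_rate = tables.exit[state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= t_total:
            break
        cum = tables.cum[state]
        new_state = bisect_left(cum, rng.random() * cum[-1])
        events.append(Event(t, state, new_state))
        state = new_state
    return state, events


def simulate(tree: Tree, spec: MMMSpec, n_sites: int, seed: int) -> SimulationResult:
    """Simulate an alignment of ``n_sites`` sites with full hidden truth."""
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    compound = compose_compound_generator(spec)
    lam = compound.generator
    tables = _JumpTables(lam)
    stat_cum = np.cumsum(compound.stationary)
    s_count = compound.n_states
    n_nodes = tree.n_nodes
    node_states = np.zeros((n_nodes, n_sites), dtype=int)
    events: dict = {}
    cats = None
    cat_rates = None
    if spec.asrv is not None:
        cats = np.zeros(n_sites, dtype=int)
        cat_rates = spec.asrv.category_rates
        cat_cum = np.cumsum(spec.asrv.category_weights)

    for site in range(n_sites):
        rng = _site_rng(seed, site)
        rate = 1.0
        if spec.asrv is not None:
            c = int(np.searchsorted(cat_cum, rng.random() * cat_cum[-1]))
            cats[site] = c
            rate = float(cat_rates[c])
        root_state = int(np.searchsorted(stat_cum, rng.random() * stat_cum[-1]))
        node_states[tree.root, site] = root_state
        for v in tree.preorder():
            if v == tree.root:
                continue
            parent_state = node_states[tree.parent[v], site]
            end, evts = _gillespie(rng, tables, parent_state,
                                   rate * tree.branch_lengths[v])
            node_states[v, site] = end
            if evts:
                events[(v, site)] = evts

    labels = spec.state_labels
    seqs = []
    taxa = []
    for i, v in enumerate(tree.tip_nodes):
        chars = node_states[v] % s_count
        seqs.append("".join(labels[c] for c in chars))
        taxa.append(tree.tip_labels[i])
    aln = Alignment(taxa, seqs, alphabet=labels)
    return SimulationResult(aln, node_states, events, cats, seed, tree, compound)


def switch_count_truth(result: SimulationResult):
    """Per-site counts of between-model events, plus their histogram.

    Counts every switching event on every branch (not just endpoint
    differences), summed over the tree.
    """
    n_sites = result.alignment.n_sites
    s_count = result.compound.n_states
    counts = np.zeros(n_sites, dtype=int)
    for (v, site), evts in result.events.items():
        counts[site] += sum(e.is_model_switch(s_count) for e in evts)
    hist = np.bincount(counts)
    return counts, hist


def substitution_count_truth(result: SimulationResult) -> np.ndarray:
    """Per-site counts of within-model character-changing events."""
    n_sites = result.alignment.n_sites
    s_count = result.compound.n_states
    counts = np.zeros(n_sites, dtype=int)
    for (v, site), evts in result.events.items():
        counts[site] += sum(
            (not e.is_model_switch(s_count))
            and (e.from_state % s_count != e.to_state % s_count)
            for e in evts
        )
    return counts


# ---------------------------------------------------------------------------
# benchmark panels
# ---------------------------------------------------------------------------

def make_benchmark_suite(config: dict, seed: int, out_dir) -> list[Path]:
    """Write simulated fixture panels (tree, FASTA, truth, config) to disk.

    ``config`` maps panel names to ``{"spec": MMMSpec-or-dict, "n_taxa": int
    or "tree": newick, "n_sites": int}``. Outputs per panel: ``<name>.nwk``,
    ``<name>.fasta``, ``<name>.truth.tsv`` (site, node, model index),
    ``<name>.events.tsv`` and ``<name>.config.json``. Deterministic given
    the seed.
    """
    from .mmm import spec_from_dict
    from .phylo import read_tree

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (name, panel) in enumerate(sorted(config.items())):
        spec = panel["spec"]
        if isinstance(spec, dict):
            spec = spec_from_dict(spec)
        panel_seed = seed + 1000 * i
        if "tree" in panel:
            tree = read_tree(panel["tree"])
        else:
            tree = random_tree(panel["n_taxa"], np.random.default_rng(panel_seed))
        res = simulate(tree, spec, panel["n_sites"], panel_seed + 1)

        tree_path = out / f"{name}.nwk"
        tree_path.write_text(write_tree(tree) + "\n")
        aln_path = out / f"{name}.fasta"
        write_alignment(res.alignment, aln_path)
        truth_path = out / f"{name}.truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("site\tnode\tmodel\n")
            models = res.model_states()
            for site in range(res.alignment.n_sites):
                for v in range(tree.n_nodes):
                    fh.write(f"{site}\t{tree.node_names[v]}\t{models[v, site]}\n")
        ev_path = out / f"{name}.events.tsv"
        with open(ev_path, "w") as fh:
            fh.write("node\tsite\ttime\tfrom\tto\n")
            for (v, site), evts in sorted(res.events.items()):
                for e in evts:
                    fh.write(f"{tree.node_names[v]}\t{site}\t{e.time:.9g}\t"
                             f"{e.from_state}\t{e.to_state}\n")
        cfg_path = out / f"{name}.config.json"
        cfg_path.write_text(json.dumps({
            "spec": spec_to_dict(spec),
            "n_sites": panel["n_sites"],
            "seed": panel_seed,
        }, indent=2))
        written += [tree_path, aln_path, truth_path, ev_path, cfg_path]
    return written
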