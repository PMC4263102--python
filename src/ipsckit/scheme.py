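"""Markov gating schemes for ligand-gated channels.

The default model is a seven-node Jones–Westbrook-style GABA-A scheme:
an unbound state U, mono- and bi-liganded closed states B1/B2, open states
O1/O2 and desensitized states D1/D2::

            on1*C      on2*C
        U  <====>  B1  <====>  B2
           koff1   |   2*koff2  |
                b1 | a1      b2 | a2
                   O1           O2
             (B1 <-> D1,  B2 <-> D2)

Agonist-dependent rates (binding) are given in M^-1 s^-1 and are multiplied
by the instantaneous agonist concentration; all other rates are first-order
in s^-1.  Open states carry the unitary current.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Tuple

import numpy as np

Edge = Tuple[str, str]


@dataclass(frozen=True)
class AgonistPulse:
    """Square agonist application: ``concentration`` M for ``duration`` ms.

    Default is the rapid-application protocol: a 1-ms pulse of 1 mM GABA.
    """

    concentration: float = 1e-3
    onset: float = 0.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    def concentration_at(self, t_ms: float) -> float:
        if self.onset <= t_ms < self.onset + self.duration:
            return self.concentration
        return 0.0


@dataclass(frozen=True)
class ChannelScheme:
    """A first-order Markov gating scheme.

    Parameters
    ----------
    state_names:
        All kinetic states.
    agonist_rates:
        Binding transitions, (from, to) -> rate coefficient in M^-1 s^-1.
        Effective rate = coefficient x agonist concentration (M).
    fixed_rates:
        Concentration-independent transitions, (from, to) -> rate in s^-1.
    open_states:
        Conducting states.
    unitary_current:
        Current per open channel in pA (negative for inward Cl- flux at
        hyperpolarized potentials with high internal Cl-).
    """

    state_names: Tuple[str, ...]
    agonist_rates: Dict[Edge, float]
    fixed_rates: Dict[Edge, float]
    open_states: FrozenSet[str]
    unitary_current: float = -1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "open_states", frozenset(self.open_states))
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        states = set(self.state_names)
        if len(states) != len(self.state_names):
            raise ValueError("duplicate state names")
        for rates, kind in ((self.agonist_rates, "agonist"), (self.fixed_rates, "fixed")):
            for (a, b), r in rates.items():
                if a not in states or b not in states:
                    raise ValueError(f"{kind} rate references unknown state: {(a, b)}")
                if r < 0:
                    raise ValueError(f"negative {kind} rate on {(a, b)}")
        if not self.open_states <= states:
            raise ValueError("open_states must be a subset of state_names")
        # connectivity of the undirected transition graph
        adj = {s: set() for s in states}
        for (a, b) in list(self.agonist_rates) + list(self.fixed_rates):
            adj[a].add(b)
            adj[b].add(a)
        seen = {self.state_names[0]}
        stack = [self.state_names[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != states:
            raise ValueError("transition graph is not connected")
        if len(self.unbound_states()) != 1:
            raise ValueError("scheme must have exactly one unbound state")

    def unbound_states(self) -> Tuple[str, ...]:
        """States with an outgoing binding step but no incoming one."""
        has_in = {b for (_, b) in self.agonist_rates}
        has_out = {a for (a, _) in self.agonist_rates}
        return tuple(s for s in self.state_names if s in has_out and s not in has_in)

    @property
    def resting_state(self) -> str:
        return self.unbound_states()[0]

    def unbinding_edges(self) -> Tuple[Edge, ...]:
        """Fixed-rate edges that reverse a binding step."""
        binding = set(self.agonist_rates)
        return tuple((a, b) for (a, b) in self.fixed_rates if (b, a) in binding)

    # -- numerics -------------------------------------------------------

    def index(self, state: str) -> int:
        return self.state_names.index(state)

    def rate_matrix(self, concentration: float) -> np.ndarray:
        """Generator matrix Q (rows = from-state); Q[i, j] is the i->j rate in s^-1."""
        n = len(self.state_names)
        idx = {s: i for i, s in enumerate(self.state_names)}
        Q = np.zeros((n, n))
        for (a, b), r in self.fixed_rates.items():
            Q[idx[a], idx[b]] += r
        for (a, b), r in self.agonist_rates.items():
            Q[idx[a], idx[b]] += r * concentration
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def open_index(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.state_names) if s in self.open_states])

    def max_exit_rate(self, concentration: float) -> float:
        Q = self.rate_matrix(concentration)
        return float(np.max(-np.diag(Q)))

    # -- modified copies ------------------------------------------------

    def scale_rates(self, factor: float, which: str = "all") -> "ChannelScheme":
        """Return a copy with a subset of rates multiplied by ``factor``.

        ``which`` is one of ``"all"`` (every rate), ``"binding"`` (agonist
        rates), ``"unbinding"`` (fixed rates reversing a binding step).
        """
        ag = dict(self.agonist_rates)
        fx = dict(self.fixed_rates)
        if which == "all":
            ag = {e: r * factor for e, r in ag.items()}
            fx = {e: r * factor for e, r in fx.items()}
        elif which == "binding":
            ag = {e: r * factor for e, r in ag.items()}
        elif which == "unbinding":
            unb = set(self.unbinding_edges())
            fx = {e: (r * factor if e in unb else r) for e, r in fx.items()}
        else:
            raise ValueError(f"unknown rate subset {which!r}")
        return replace(self, agonist_rates=ag, fixed_rates=fx)


def default_scheme(unitary_current: float = -1.0) -> ChannelScheme:
    """Seven-state GABA-A gating scheme with literature-plausible rates.

    The magnitudes follow the Jones–Westbrook family (fast bi-liganded
    opening, prominent bi-liganded desensitization, slow mono-liganded
    desensitization).  These defaults are a starting point; analyses that
    need a specific macroscopic decay call :func:`ipsckit.synth.calibrate_scheme`.
    """
    return ChannelScheme(
        state_names=("U", "B1", "B2", "O1", "O2", "D1", "D2"),
        agonist_rates={("U", "B1"): 1.0e7, ("B1", "B2"): 5.0e6},
        fixed_rates={
            ("B1", "U"): 1.0e3,
            ("B2", "B1"): 2.0e3,
            ("B1", "O1"): 200.0,
            ("O1", "B1"): 1.1e3,
            ("B2", "O2"): 2.5e3,
            ("O2", "B2"): 400.0,
            ("B1", "D1"): 13.0,
            ("D1", "B1"): 1.3,
            ("B2", "D2"): 1.25e3,
            ("D2", "B2"): 140.0,
        },
        open_states=frozenset({"O1", "O2"}),
        unitary_current=unitary_current,
    )


def write_scheme_text(scheme: ChannelScheme, path) -> None:
    """Plain-text key-value scheme format (states, rates, open set, unitary)."""
    lines = []
    for s in scheme.state_names:
        flag = " open" if s in scheme.open_states else ""
        lines.append(f"state {s}{flag}")
    for (a, b), r in scheme.fixed_rates.items():
        lines.append(f"rate {a} {b} {r:.12g}")
    for (a, b), r in scheme.agonist_rates.items():
        lines.append(f"rate {a} {b} {r:.12g} agonist")
    lines.append(f"unitary_current {scheme.unitary_current:.12g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scheme_text(path) -> ChannelScheme:
    states: list = []
    open_states = set()
    agonist: Dict[Edge, float] = {}
    fixed: Dict[Edge, float] = {}
    unitary = -1.0
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "state":
                states.append(parts[1])
                if "open" in parts[2:]:
                    open_states.add(parts[1])
            elif parts[0] == "rate":
                a, b, r = parts[1], parts[2], float(parts[3])
                if "agonist" in parts[4:]:
                    agonist[(a, b)] = r
                else:
                    fixed[(a, b)] = r
            elif parts[0] == "unitary_current":
                unitary = float(parts[1])
            else:
                raise ValueError(f"unrecognized line in scheme file: {raw!r}")
    return ChannelScheme(tuple(states), agonist, fixed, frozenset(open_states), unitary)
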