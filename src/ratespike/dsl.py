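"""Equation-oriented model description language.

Neuron and synapse models are declared as plain-text blocks of parameters and
equations, in a syntax close to natural mathematical notation:

* parameters: ``name = value [: flags]``, one per line or ``;``-separated.
  The ``population`` / ``postsynaptic`` flags mark a parameter as shared
  (one value per population or per post-synaptic neuron); ``int`` / ``bool``
  change the dtype from the default double float.
* variables: either regular assignments (``r = ...`` with ``=``, ``+=``, ...)
  or first-order ODEs written with a ``dX/dt`` term anywhere in the equation
  (``tau*dv/dt + v = E`` is normalized to ``dv/dt = (E - v)/tau``).
  Flags capture the initial value (``init=``), bounds (``min=``/``max=``),
  locality and the numerical method (``explicit``, ``implicit``,
  ``exponential``, ``midpoint``, ``event-driven``).

Expressions may reference the weighted input sum ``sum(target)`` (rate-coded),
conductances ``g_target`` (spiking), random draws (``Uniform(-1, 1)``,
``Normal(0, 1)``, ...), global operations (``mean(pre.r)``), pre-/post-synaptic
attributes (``pre.r``, ``post.v`` — synapses only), the time ``t`` (ms) and the
step ``dt``, and Python-style conditionals (``if cond: a else: b``, which may
be nested).  Parsing produces sympy expression trees; special vocabulary is
extracted with regular expressions and replaced by typed placeholder symbols
before sympy sees the text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import sympy as sp
from sympy.parsing.sympy_parser import (
    parse_expr,
    standard_transformations,
    convert_xor,
)


class EquationError(ValueError):
    """Raised when a model text block cannot be parsed or validated."""


# --------------------------------------------------------------------------
# vocabulary
# --------------------------------------------------------------------------

#: math functions accepted in equations (C math library names, plus clip)
MATH_FUNCTIONS = {
    "cos": sp.cos, "sin": sp.sin, "tan": sp.tan,
    "acos": sp.acos, "asin": sp.asin, "atan": sp.atan, "atan2": sp.atan2,
    "cosh": sp.cosh, "sinh": sp.sinh, "tanh": sp.tanh,
    "exp": sp.exp, "log": sp.log, "sqrt": sp.sqrt,
    "fabs": sp.Abs, "abs": sp.Abs, "pow": sp.Pow,
    "floor": sp.floor, "ceil": sp.ceiling,
    "clip": sp.Function("clip"),
}

#: random number distributions usable inside equations
DISTRIBUTIONS = ("Uniform", "Normal", "LogNormal", "Exponential", "Gamma")

#: names with fixed semantics that models may not declare
RESERVED_NAMES = {"t", "dt", "pre", "post", "g_target"}

_IDENT = r"[A-Za-z_]\w*"
_TRANSFORMS = standard_transformations + (convert_xor,)

_VALID_FLAG = re.compile(
    r"^\s*(population|postsynaptic|int|bool|explicit|implicit|exponential|"
    r"midpoint|event-driven|event_driven|init\s*=.+|min\s*=.+|max\s*=.+|"
    r"proba\s*=.+|w\s*=.+|d\s*=.+)\s*$"
)


@dataclass
class RandomSpec:
    """A random draw appearing in an equation; re-drawn each step per unit."""

    dist: str
    args: tuple

    def draw(self, rng, size):
        a = self.args
        if self.dist == "Uniform":
            return rng.uniform(a[0], a[1], size)
        if self.dist == "Normal":
            return rng.normal(a[0], a[1], size)
        if self.dist == "LogNormal":
            return rng.lognormal(a[0], a[1], size)
        if self.dist == "Exponential":
            return rng.exponential(a[0], size)
        if self.dist == "Gamma":
            scale = a[1] if len(a) > 1 else 1.0
            return rng.gamma(a[0], scale, size)
        raise EquationError(f"unknown distribution {self.dist}")


@dataclass
class GlobalOp:
    """A population-wide reduction such as mean(pre.r) or max(r)."""

    op: str               # mean | min | max
    side: str | None      # 'pre' | 'post' | None (own population)
    var: str


@dataclass
class Vocab:
    """Special vocabulary extracted from one expression."""

    randoms: dict = field(default_factory=dict)     # placeholder -> RandomSpec
    sums: dict = field(default_factory=dict)        # placeholder -> target
    globalops: dict = field(default_factory=dict)   # placeholder -> GlobalOp
    prepost: dict = field(default_factory=dict)     # placeholder -> (side, var)

    def merge(self, other: "Vocab") -> None:
        self.randoms.update(other.randoms)
        self.sums.update(other.sums)
        self.globalops.update(other.globalops)
        self.prepost.update(other.prepost)


# --------------------------------------------------------------------------
# low-level text helpers
# --------------------------------------------------------------------------

def _strip_comments(text: str) -> str:
    return re.sub(r"#[^\n]*", "", text)


_CONT_START = re.compile(r"^(?:[:+\-*/^=)<>,]|else\b|and\b|or\b|if\b)")
_CONT_END = re.compile(r"(?:[:+\-*/^=(,<>]|\belse|\band|\bor|\bif)$")


def _split_items(text: str) -> list:
    """Split a block into statements on newlines and semicolons.

    A line is joined to the previous one when parentheses are unbalanced or
    when either side ends/starts with an operator (multi-line equations).
    """
    text = _strip_comments(text)
    merged = []
    for line in text.split("\n"):
        s = line.strip()
        if not s:
            continue
        if merged and (merged[-1].count("(") != merged[-1].count(")")
                       or _CONT_START.match(s)
                       or _CONT_END.search(merged[-1])):
            merged[-1] += " " + s
        else:
            merged.append(s)
    items = []
    for line in merged:
        for piece in line.split(";"):
            piece = piece.strip()
            if piece:
                items.append(piece)
    for it in items:
        if it.count("(") != it.count(")"):
            raise EquationError(f"unbalanced parentheses in {it!r}")
    return items


def _find_matching(text: str, open_idx: int) -> int:
    depth = 0
    for i in range(open_idx, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return i
    raise EquationError(f"unbalanced parentheses in {text!r}")


def _split_top(text: str, sep_word: str) -> list:
    """Split on a word separator at parenthesis depth 0."""
    parts, depth, last, i = [], 0, 0, 0
    pat = re.compile(r"\b%s\b" % sep_word)
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0:
            m = pat.match(text, i)
            if m:
                parts.append(text[last:i])
                last = i = m.end()
                continue
        i += 1
    parts.append(text[last:])
    return parts


def _split_flags(item: str) -> tuple:
    """Split ``expr : flags`` on the right-most depth-0 colon whose tail
    consists solely of valid flags (conditionals also contain colons)."""
    depth = 0
    colon = None
    for i, ch in enumerate(item):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == ":" and depth == 0:
            colon = i
    if colon is None:
        return item, []
    tail = item[colon + 1:]
    flags = [f.strip() for f in tail.split(",") if f.strip()]
    if flags and all(_VALID_FLAG.match(f) for f in flags):
        return item[:colon], flags
    return item, []


def _parse_number(text: str):
    t = text.strip()
    if t in ("True", "true"):
        return True
    if t in ("False", "false"):
        return False
    try:
        val = sp.sympify(t)
        if not val.is_number:
            raise ValueError
        return float(val)
    except Exception:
        raise EquationError(f"cannot parse value {text!r}") from None


# --------------------------------------------------------------------------
# expression parsing
# --------------------------------------------------------------------------

def _replace_prepost(text: str, vocab: Vocab, scope: str) -> str:
    def repl(m):
        side, var = m.group(1), m.group(2)
        if scope != "synapse":
            raise EquationError(
                f"{side}.{var}: pre./post. references are only valid in "
                "synapse models"
            )
        ph = f"_{side}_{var}"
        vocab.prepost[ph] = (side, var)
        return ph

    return re.sub(r"\b(pre|post)\.(%s)" % _IDENT, repl, text)


def _extract_randoms(text: str, vocab: Vocab) -> str:
    pat = re.compile(r"\b(%s)\s*\(" % "|".join(DISTRIBUTIONS))
    while True:
        m = pat.search(text)
        if m is None:
            return text
        close = _find_matching(text, m.end() - 1)
        args_txt = text[m.end():close]
        args = tuple(_parse_number(a) for a in args_txt.split(","))
        ph = f"_rand_{len(vocab.randoms)}"
        vocab.randoms[ph] = RandomSpec(m.group(1), args)
        text = text[:m.start()] + ph + text[close + 1:]


def _extract_global_ops(text: str, vocab: Vocab) -> str:
    # only single-identifier arguments are reductions; anything else is an
    # (unknown) function call and rejected later
    pat = re.compile(r"\b(mean|min|max)\s*\(\s*(_?%s)\s*\)" % _IDENT)

    def repl(m):
        op, ref = m.group(1), m.group(2)
        if ref.startswith("_pre_"):
            side, var = "pre", ref[5:]
        elif ref.startswith("_post_"):
            side, var = "post", ref[6:]
        else:
            side, var = None, ref
        ph = f"_{op}_{ref.lstrip('_')}"
        vocab.globalops[ph] = GlobalOp(op, side, var)
        return ph

    return pat.sub(repl, text)


def _extract_sums(text: str, vocab: Vocab, scope: str) -> str:
    def repl(m):
        target = m.group(1)
        ph = f"_sum_{target}"
        vocab.sums[ph] = target
        return ph

    return re.sub(r"\bsum\s*\(\s*(%s)\s*\)" % _IDENT, repl, text)


def _check_unknown_functions(text: str) -> None:
    for m in re.finditer(r"(%s)\s*\(" % _IDENT, text):
        name = m.group(1)
        if name not in MATH_FUNCTIONS and name != "Piecewise":
            raise EquationError(f"unknown function {name!r}")


def _parse_arith(text: str) -> sp.Expr:
    text = text.strip()
    if not text:
        raise EquationError("empty expression")
    _check_unknown_functions(text)
    local = dict(MATH_FUNCTIONS)
    local["pi"] = sp.pi
    local["Piecewise"] = sp.Piecewise
    for name in set(re.findall(_IDENT, text)):
        if name not in local and name not in ("True", "False"):
            local[name] = sp.Symbol(name)
    try:
        return parse_expr(text, transformations=_TRANSFORMS, local_dict=local)
    except EquationError:
        raise
    except Exception as exc:
        raise EquationError(f"cannot parse expression {text!r}: {exc}") from None


_CMP_OPS = (
    ("<=", sp.Le), (">=", sp.Ge), ("==", sp.Eq), ("!=", sp.Ne),
    ("<", sp.Lt), (">", sp.Gt),
)


def _parse_bool(text: str):
    t = text.strip()
    while t.startswith("(") and _find_matching(t, 0) == len(t) - 1:
        t = t[1:-1].strip()
    if not t:
        raise EquationError("empty condition")
    parts = _split_top(t, "or")
    if len(parts) > 1:
        return sp.Or(*[_parse_bool(p) for p in parts])
    parts = _split_top(t, "and")
    if len(parts) > 1:
        return sp.And(*[_parse_bool(p) for p in parts])
    m = re.match(r"\s*not\b", t)
    if m:
        return sp.Not(_parse_bool(t[m.end():]))
    # comparison at depth 0
    depth = 0
    i = 0
    while i < len(t):
        ch = t[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0:
            for op, cls in _CMP_OPS:
                if t.startswith(op, i):
                    lhs, rhs = t[:i], t[i + len(op):]
                    return cls(_parse_arith(lhs), _parse_arith(rhs))
        i += 1
    if t in ("true", "True"):
        return sp.true
    if t in ("false", "False"):
        return sp.false
    if re.fullmatch(_IDENT, t):
        return sp.Symbol(t)   # boolean attribute
    raise EquationError(f"condition {text!r} is not boolean")


def _split_conditional(text: str) -> tuple:
    """Split ``if C: A else: B`` into its three parts, honoring nesting."""
    s = text.lstrip()
    if not s.startswith("if"):
        raise EquationError(f"not a conditional: {text!r}")
    s = s[2:]
    depth = 0
    cond = None
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == ":" and depth == 0:
            cond, rest = s[:i], s[i + 1:]
            break
    if cond is None:
        raise EquationError(f"missing ':' in conditional {text!r}")
    depth = nested = 0
    i = 0
    while i < len(rest):
        m = re.match(_IDENT, rest[i:])
        if m and depth == 0:
            word = m.group(0)
            if word == "if":
                nested += 1
            elif word == "else":
                if nested == 0:
                    true_part = rest[:i]
                    after = rest[i + 4:].lstrip()
                    if not after.startswith(":"):
                        raise EquationError(
                            f"missing ':' after else in {text!r}")
                    return cond, true_part, after[1:]
                nested -= 1
        if m:
            i += m.end()
            continue
        if rest[i] == "(":
            depth += 1
        elif rest[i] == ")":
            depth -= 1
        i += 1
    raise EquationError(f"'if' without matching 'else' in {text!r}")


def _parse_with_conditionals(text: str) -> sp.Expr:
    replacements = {}
    pat = re.compile(r"\(\s*if\b")
    while True:
        m = pat.search(text)
        if m is None:
            break
        close = _find_matching(text, m.start())
        inner = text[m.start() + 1:close]
        ph = sp.Symbol(f"_cond_{len(replacements)}")
        replacements[ph] = _parse_conditional_text(inner)
        text = text[:m.start()] + str(ph) + text[close + 1:]
    stripped = text.strip()
    if re.match(r"if\b", stripped):
        expr = _parse_conditional_text(stripped)
    else:
        expr = _parse_arith(text)
    if replacements:
        expr = expr.xreplace(replacements)
    return expr


def _parse_conditional_text(text: str) -> sp.Expr:
    cond, true_part, false_part = _split_conditional(text)
    cond_e = _parse_bool(cond)

    def branch(s):
        s = s.strip()
        if re.match(r"if\b", s):
            return _parse_conditional_text(s)
        return _parse_with_conditionals(s)

    return sp.Piecewise((branch(true_part), cond_e),
                        (branch(false_part), sp.true))


def parse_expression(text: str, scope: str = "neuron"):
    """Parse one right-hand side into ``(sympy expression, Vocab)``.

    scope is ``'neuron'`` or ``'synapse'``; pre./post. references are only
    legal in synapse scope.
    """
    vocab = Vocab()
    txt = _replace_prepost(text, vocab, scope)
    txt = _extract_randoms(txt, vocab)
    txt = _extract_global_ops(txt, vocab)
    txt = _extract_sums(txt, vocab, scope)
    return _parse_with_conditionals(txt), vocab


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class ParameterSpec:
    """One named constant of a model, with locality and dtype."""

    name: str
    value: float
    locality: str = "local"      # 'local' (per unit) | 'shared'
    dtype: str = "real"          # 'real' | 'int' | 'bool'

    def to_dict(self):
        return {"name": self.name, "value": self.value,
                "locality": self.locality, "dtype": self.dtype}


def parse_parameters(text: str) -> list:
    """Parse a parameters block into a list of :class:`ParameterSpec`."""
    specs = []
    seen = set()
    for item in _split_items(text or ""):
        body, flags = _split_flags(item)
        m = re.fullmatch(r"\s*(%s)\s*=\s*(.+?)\s*" % _IDENT, body)
        if m is None:
            raise EquationError(f"cannot parse parameter {item!r}")
        name = m.group(1)
        if name in seen:
            raise EquationError(f"duplicate parameter {name!r}")
        if name in RESERVED_NAMES:
            raise EquationError(f"{name!r} is a reserved name")
        seen.add(name)
        value = _parse_number(m.group(2))
        locality, dtype = "local", "real"
        for f in flags:
            if f in ("population", "postsynaptic"):
                locality = "shared"
            elif f == "int":
                dtype = "int"
            elif f == "bool":
                dtype = "bool"
            else:
                raise EquationError(f"unknown parameter flag {f!r}")
        if dtype == "bool":
            value = bool(value)
        elif dtype == "int":
            value = int(value)
        specs.append(ParameterSpec(name, value, locality, dtype))
    return specs


# --------------------------------------------------------------------------
# variables
# --------------------------------------------------------------------------

_AUG_OPS = ("+=", "-=", "*=", "/=")
_ODE_PAT = re.compile(r"\bd(%s)\s*/\s*dt\b" % _IDENT)


@dataclass
class VariableSpec:
    """One time-evolving quantity: an assignment or a first-order ODE."""

    name: str
    kind: str                    # 'assignment' | 'ode'
    rhs: sp.Expr                 # for ODEs: the gradient dX/dt = rhs
    vocab: Vocab
    op: str = "="                # augmented op, assignments only
    init: float = 0.0
    min_bound: float | None = None
    max_bound: float | None = None
    locality: str = "local"
    method: str = "inherit"
    dtype: str = "real"
    raw: str = ""

    def to_dict(self):
        return {"name": self.name, "raw": self.raw}

    def __eq__(self, other):
        if not isinstance(other, VariableSpec):
            return NotImplemented
        return (
            self.name == other.name and self.kind == other.kind
            and self.op == other.op and self.init == other.init
            and self.min_bound == other.min_bound
            and self.max_bound == other.max_bound
            and self.locality == other.locality
            and self.method == other.method and self.dtype == other.dtype
            and sp.simplify(self.rhs - other.rhs) == 0
        )


def normalize_ode(equation_text: str, scope: str = "neuron"):
    """Normalize an ODE to canonical gradient form.

    ``"tau*dv/dt + v = E"`` becomes ``("v", (E - v)/tau)``.  The equation
    must contain exactly one ``dX/dt`` term, linearly.
    """
    names = set(_ODE_PAT.findall(equation_text))
    if len(names) != 1:
        raise EquationError(
            f"equation must contain exactly one dX/dt term: {equation_text!r}")
    var = names.pop()
    grad_sym = sp.Symbol(f"_grad_{var}")
    txt = _ODE_PAT.sub(str(grad_sym), equation_text)
    if "=" not in txt:
        raise EquationError(f"ODE is not an equation: {equation_text!r}")
    lhs_txt, rhs_txt = txt.split("=", 1)
    vocab = Vocab()
    lhs_txt = _replace_prepost(lhs_txt, vocab, scope)
    rhs_txt = _replace_prepost(rhs_txt, vocab, scope)
    rhs_txt = _extract_randoms(rhs_txt, vocab)
    rhs_txt = _extract_global_ops(rhs_txt, vocab)
    rhs_txt = _extract_sums(rhs_txt, vocab, scope)
    lhs = _parse_arith(lhs_txt)
    rhs = _parse_with_conditionals(rhs_txt)
    eq = lhs - rhs
    try:
        a, b = sp.linear_eq_to_matrix([eq], [grad_sym])
    except Exception:
        raise EquationError(
            f"dX/dt appears nonlinearly in {equation_text!r}") from None
    coeff = sp.simplify(a[0, 0])
    if coeff == 0:
        raise EquationError(f"dX/dt vanishes from {equation_text!r}")
    grad = sp.simplify(b[0] / coeff)
    return var, grad, vocab


def parse_variables(text: str, scope: str = "neuron") -> list:
    """Parse an equations block into an ordered list of VariableSpec."""
    specs = []
    seen = set()
    for item in _split_items(text or ""):
        body, flags = _split_flags(item)
        spec = _parse_variable_item(body, flags, scope)
        if spec.name in seen:
            raise EquationError(f"duplicate variable {spec.name!r}")
        seen.add(spec.name)
        spec.raw = item
        specs.append(spec)
    return specs


def _parse_variable_item(body: str, flags: list, scope: str) -> VariableSpec:
    if _ODE_PAT.search(body):
        # augmented operators are illegal on ODEs
        lhs_probe = body.split("=", 1)[0]
        if any(lhs_probe.rstrip().endswith(op[0]) for op in _AUG_OPS):
            raise EquationError(f"ODE with augmented operator: {body!r}")
        name, grad, vocab = normalize_ode(body, scope)
        spec = VariableSpec(name, "ode", grad, vocab)
    else:
        m = re.match(r"\s*(%s)\s*(\+=|-=|\*=|/=|=)\s*(.+)$" % _IDENT,
                     body, re.S)
        if m is None:
            raise EquationError(f"cannot parse equation {body!r}")
        name, op, rhs_txt = m.group(1), m.group(2), m.group(3)
        rhs, vocab = parse_expression(rhs_txt, scope)
        spec = VariableSpec(name, "assignment", rhs, vocab, op=op)
    if spec.name in RESERVED_NAMES:
        raise EquationError(f"{spec.name!r} is a reserved name")
    for f in flags:
        key = f.split("=")[0].strip()
        if key == "init":
            spec.init = _parse_number(f.split("=", 1)[1])
        elif key == "min":
            spec.min_bound = _parse_number(f.split("=", 1)[1])
        elif key == "max":
            spec.max_bound = _parse_number(f.split("=", 1)[1])
        elif f in ("population", "postsynaptic"):
            spec.locality = "shared"
        elif f in ("explicit", "implicit", "exponential", "midpoint"):
            spec.method = f
        elif f in ("event-driven", "event_driven"):
            spec.method = "event-driven"
        elif f == "int":
            spec.dtype = "int"
        elif f == "bool":
            spec.dtype = "bool"
        else:
            raise EquationError(f"unknown flag {f!r}")
    if spec.method == "event-driven" and spec.kind != "ode":
        raise EquationError(
            f"event-driven method requires an ODE ({spec.name})")
    if (spec.min_bound is not None and spec.max_bound is not None
            and spec.min_bound > spec.max_bound):
        raise EquationError(f"min > max for variable {spec.name!r}")
    return spec


# --------------------------------------------------------------------------
# conditions and statements
# --------------------------------------------------------------------------

@dataclass
class Condition:
    """A boolean expression plus an optional all-quantifier."""

    expr: sp.Basic
    vocab: Vocab
    quantifier: str = "any"      # 'any' | 'all'


def parse_condition(text: str, scope: str = "neuron") -> Condition:
    """Parse a boolean condition; a trailing ``: all`` sets the quantifier."""
    txt = _strip_comments(text).strip()
    quant = "any"
    m = re.search(r":\s*(all|any)\s*$", txt)
    if m:
        quant = m.group(1)
        txt = txt[:m.start()]
    vocab = Vocab()
    txt = _replace_prepost(txt, vocab, scope)
    txt = _extract_sums(txt, vocab, scope)
    expr = _parse_bool(txt)
    if expr not in (sp.true, sp.false) and not isinstance(
            expr, (sp.logic.boolalg.Boolean,)):
        raise EquationError(f"condition {text!r} is not boolean")
    return Condition(expr, vocab, quant)


@dataclass
class Statement:
    """One event statement, e.g. ``g_target += w`` in pre_spike."""

    target: str
    op: str
    rhs: sp.Expr
    vocab: Vocab
    raw: str = ""


def parse_statements(text: str, scope: str = "neuron") -> list:
    stmts = []
    for item in _split_items(text or ""):
        m = re.match(r"\s*(%s)\s*(\+=|-=|\*=|/=|=)\s*(.+)$" % _IDENT,
                     item, re.S)
        if m is None:
            raise EquationError(f"cannot parse statement {item!r}")
        rhs, vocab = parse_expression(m.group(3), scope)
        stmts.append(Statement(m.group(1), m.group(2), rhs, vocab, raw=item))
    return stmts


@dataclass
class StructuralRule:
    """Runtime synapse creation/pruning rule (see extensions module)."""

    kind: str                    # 'creating' | 'pruning'
    condition: sp.Basic
    vocab: Vocab
    proba: float = 1.0
    w: float = 0.0
    d: float | None = None
    raw: str = ""


def parse_structural_rule(text: str, kind: str) -> StructuralRule:
    body, flags = _split_flags(_strip_comments(text).strip())
    vocab = Vocab()
    txt = _replace_prepost(body, vocab, "synapse")
    expr = _parse_bool(txt)
    rule = StructuralRule(kind, expr, vocab, raw=text)
    for f in flags:
        key, _, val = f.partition("=")
        key = key.strip()
        if key == "proba":
            rule.proba = float(_parse_number(val))
        elif key == "w":
            rule.w = float(_parse_number(val))
        elif key == "d":
            rule.d = float(_parse_number(val))
        else:
            raise EquationError(f"unknown structural rule flag {f!r}")
    return rule


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

def _declared_names(params, variables):
    return ({p.name for p in params} | {v.name for v in variables})


def _expr_symbols(expr) -> set:
    return {str(s) for s in expr.free_symbols}


class Neuron:
    """A neuron model: parameters, variables and (for spiking neurons) the
    spike condition, reset statements and refractory period.

    A model is spiking iff ``spike`` is given; otherwise it is rate-coded and
    must declare a variable ``r`` (the instantaneous firing rate read by
    post-synaptic neurons).
    """

    def __init__(self, parameters="", equations="", spike=None, reset=None,
                 refractory=None, name=None, description=None):
        self._source = {
            "parameters": parameters, "equations": equations,
            "spike": spike, "reset": reset, "refractory": refractory,
            "name": name, "description": description,
        }
        self.name = name
        self.description = description
        self.parameters = parse_parameters(parameters)
        self.variables = parse_variables(equations, scope="neuron")
        self.spike_condition = (
            parse_condition(spike, scope="neuron") if spike else None)
        self.reset_statements = (
            parse_statements(reset, scope="neuron") if reset else [])
        if refractory is not None and not isinstance(refractory, str):
            refractory = float(refractory)
            if refractory < 0:
                raise EquationError("refractory period must be >= 0")
        self.refractory = refractory
        self._validate()

    @property
    def is_spiking(self) -> bool:
        return self.spike_condition is not None

    def _validate(self):
        declared = _declared_names(self.parameters, self.variables)
        var_names = {v.name for v in self.variables}
        if not self.is_spiking and "r" not in var_names:
            raise EquationError(
                "a rate-coded neuron must declare a variable named 'r'")
        exprs = [(v.rhs, v.vocab) for v in self.variables]
        if self.spike_condition is not None:
            exprs.append((self.spike_condition.expr,
                          self.spike_condition.vocab))
        for st in self.reset_statements:
            if st.target not in var_names:
                raise EquationError(
                    f"reset statement writes undeclared variable "
                    f"{st.target!r}")
            exprs.append((st.rhs, st.vocab))
        for expr, vocab in exprs:
            if vocab.sums and self.is_spiking:
                raise EquationError(
                    "sum(target) is not available in spiking neurons; "
                    "use g_target")
            for name in _expr_symbols(expr):
                if name in ("t", "dt") or name.startswith("_"):
                    continue
                if name in declared:
                    continue
                if name.startswith("g_"):
                    if not self.is_spiking:
                        raise EquationError(
                            f"{name}: conductances are only available in "
                            "spiking neurons; use sum(target)")
                    continue
                raise EquationError(f"undeclared name {name!r}")
        if isinstance(self.refractory, str) and \
                self.refractory not in declared:
            raise EquationError(
                f"refractory references undeclared name {self.refractory!r}")

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dict(self._source)

    @classmethod
    def from_dict(cls, d: dict) -> "Neuron":
        return cls(**d)

    def __eq__(self, other):
        if not isinstance(other, Neuron):
            return NotImplemented
        return (self.parameters == other.parameters
                and self.variables == other.variables
                and (self.spike_condition is None)
                == (other.spike_condition is None)
                and (self.spike_condition is None
                     or self.spike_condition.expr
                     == other.spike_condition.expr)
                and len(self.reset_statements) == len(other.reset_statements)
                and all(a.target == b.target and a.op == b.op
                        and sp.simplify(a.rhs - b.rhs) == 0
                        for a, b in zip(self.reset_statements,
                                        other.reset_statements))
                and self.refractory == other.refractory)


class Synapse:
    """A synapse model.

    Rate-coded synapses contribute ``psp`` (default ``w * pre.r``) to the
    post-synaptic input sum, aggregated with ``operator`` (sum/max/min/mean).
    Spiking synapses define ``pre_spike`` (default ``g_target += w``) and
    optionally ``post_spike`` event statements; a ``psp`` on a spiking
    synapse switches to continuous transmission (the psp value is summed into
    the conductance every step, as for NMDA synapses).
    """

    def __init__(self, parameters="", equations="", psp=None, operator="sum",
                 pre_spike=None, post_spike=None, creating=None, pruning=None,
                 name=None, description=None):
        self._source = {
            "parameters": parameters, "equations": equations, "psp": psp,
            "operator": operator, "pre_spike": pre_spike,
            "post_spike": post_spike, "creating": creating,
            "pruning": pruning, "name": name, "description": description,
        }
        if operator not in ("sum", "max", "min", "mean"):
            raise EquationError(f"unknown operator {operator!r}")
        self.name = name
        self.description = description
        self.parameters = parse_parameters(parameters)
        self.variables = parse_variables(equations, scope="synapse")
        self.operator = operator
        if psp is not None:
            self.psp, self.psp_vocab = parse_expression(psp, scope="synapse")
        else:
            self.psp = self.psp_vocab = None
        self.pre_spike = (
            parse_statements(pre_spike, scope="synapse") if pre_spike else [])
        self.post_spike = (
            parse_statements(post_spike, scope="synapse")
            if post_spike else [])
        self.creating_rule = (
            parse_structural_rule(creating, "creating") if creating else None)
        self.pruning_rule = (
            parse_structural_rule(pruning, "pruning") if pruning else None)
        self._validate()

    def _validate(self):
        declared = _declared_names(self.parameters, self.variables)
        declared |= {"w", "d"}   # implicitly declared for every synapse
        var_names = {v.name for v in self.variables} | {"w"}
        exprs = [(v.rhs, v.vocab) for v in self.variables]
        if self.psp is not None:
            exprs.append((self.psp, self.psp_vocab))
        for st in self.pre_spike + self.post_spike:
            if st.target != "g_target" and st.target not in var_names:
                raise EquationError(
                    f"event statement writes {st.target!r}, which is neither "
                    "a synaptic variable nor g_target")
            exprs.append((st.rhs, st.vocab))
        if self.creating_rule is not None:
            if any(s in var_names
                   for s in _expr_symbols(self.creating_rule.condition)):
                raise EquationError(
                    "creating rules may not reference per-synapse variables")
            exprs.append((self.creating_rule.condition,
                          self.creating_rule.vocab))
        if self.pruning_rule is not None:
            exprs.append((self.pruning_rule.condition,
                          self.pruning_rule.vocab))
        for expr, vocab in exprs:
            for ph, (side, var) in vocab.prepost.items():
                pass   # resolved against actual populations at build time
            for name in _expr_symbols(expr):
                if name in ("t", "dt", "g_target") or name.startswith("_"):
                    continue
                if name not in declared:
                    raise EquationError(f"undeclared name {name!r}")

    def to_dict(self) -> dict:
        return dict(self._source)

    @classmethod
    def from_dict(cls, d: dict) -> "Synapse":
        return cls(**d)

    def __eq__(self, other):
        if not isinstance(other, Synapse):
            return NotImplemented
        if not (self.parameters == other.parameters
                and self.variables == other.variables
                and self.operator == other.operator):
            return False
        if (self.psp is None) != (other.psp is None):
            return False
        if self.psp is not None and sp.simplify(self.psp - other.psp) != 0:
            return False
        for mine, theirs in ((self.pre_spike, other.pre_spike),
                             (self.post_spike, other.post_spike)):
            if len(mine) != len(theirs):
                return False
            for a, b in zip(mine, theirs):
                if not (a.target == b.target and a.op == b.op
                        and sp.simplify(a.rhs - b.rhs) == 0):
                    return False
        return True


def resolve_vocabulary(model) -> dict:
    """Collect the special vocabulary used by a model.

    Returns a dict with the input-sum targets, conductance targets, random
    specs and global operations referenced anywhere in the model, after
    validation against the model's scope (performed at construction).
    """
    vocabs = [v.vocab for v in model.variables]
    if isinstance(model, Neuron):
        if model.spike_condition is not None:
            vocabs.append(model.spike_condition.vocab)
        vocabs.extend(st.vocab for st in model.reset_statements)
    else:
        if model.psp_vocab is not None:
            vocabs.append(model.psp_vocab)
        vocabs.extend(st.vocab for st in model.pre_spike + model.post_spike)
    merged = Vocab()
    for v in vocabs:
        merged.merge(v)
    g_targets = set()
    for v in model.variables:
        for name in _expr_symbols(v.rhs):
            if name.startswith("g_") and name != "g_target":
                g_targets.add(name[2:])
    return {
        "sum_targets": set(merged.sums.values()),
        "g_targets": g_targets,
        "randoms": dict(merged.randoms),
        "globalops": dict(merged.globalops),
        "prepost": dict(merged.prepost),
    }
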