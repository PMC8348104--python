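"""Instrumented scalar arithmetic.

Architecture-neutral cost accounting: every multiplication, addition/subtraction
and division performed through :class:`CountedFloat` is tallied on an attached
:class:`OpCounter`.  This is how the package states algorithmic costs — the
Hamilton product's 16 multiplications + 12 additions, the 3x3 matrix product's
27 + 18, the constant per-sample cost of the streaming segmenter versus the
buffer-length-proportional cost of the sliding-window baseline — without
reference to any particular instruction set.

Comparisons and negation are free: they model branches and sign flips, which
cost no arithmetic in the sense used here.
"""

from __future__ import annotations


class OpCounter:
    """Tally of scalar arithmetic operations."""

    __slots__ = ("mul", "add", "div")

    def __init__(self) -> None:
        self.mul = 0  # multiplications
        self.add = 0  # additions and subtractions
        self.div = 0  # divisions

    @property
    def total(self) -> int:
        return self.mul + self.add + self.div

    def snapshot(self) -> tuple[int, int, int]:
        return (self.mul, self.add, self.div)

    def reset(self) -> None:
        self.mul = self.add = self.div = 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"OpCounter(mul={self.mul}, add={self.add}, div={self.div})"


class CountedFloat:
    """A float whose arithmetic is tallied on a shared :class:`OpCounter`.

    Duck-types as a real number for the algorithms in this package, so the very
    same code path that processes plain floats can be cost-profiled by feeding
    it counted scalars.
    """

    __slots__ = ("v", "c")

    def __init__(self, value: float, counter: OpCounter) -> None:
        self.v = float(value)
        self.c = counter

    def _val(self, other) -> float:
        return other.v if isinstance(other, CountedFloat) else float(other)

    # -- counted arithmetic -------------------------------------------------
    def __add__(self, other):
        self.c.add += 1
        return CountedFloat(self.v + self._val(other), self.c)

    __radd__ = __add__

    def __sub__(self, other):
        self.c.add += 1
        return CountedFloat(self.v - self._val(other), self.c)

    def __rsub__(self, other):
        self.c.add += 1
        return CountedFloat(self._val(other) - self.v, self.c)

    def __mul__(self, other):
        self.c.mul += 1
        return CountedFloat(self.v * self._val(other), self.c)

    __rmul__ = __mul__

    def __truediv__(self, other):
        self.c.div += 1
        return CountedFloat(self.v / self._val(other), self.c)

    def __rtruediv__(self, other):
        self.c.div += 1
        return CountedFloat(self._val(other) / self.v, self.c)

    # -- free operations ----------------------------------------------------
    def __neg__(self):
        return CountedFloat(-self.v, self.c)

    def __pos__(self):
        return self

    def __abs__(self):
        return CountedFloat(abs(self.v), self.c)

    def __float__(self) -> float:
        return self.v

    def __eq__(self, other) -> bool:
        return self.v == self._val(other)

    def __ne__(self, other) -> bool:
        return self.v != self._val(other)

    def __lt__(self, other) -> bool:
        return self.v < self._val(other)

    def __le__(self, other) -> bool:
        return self.v <= self._val(other)

    def __gt__(self, other) -> bool:
        return self.v > self._val(other)

    def __ge__(self, other) -> bool:
        return self.v >= self._val(other)

    def __hash__(self) -> int:
        return hash(self.v)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CountedFloat({self.v!r})"


def counted(values, counter: OpCounter):
    """Wrap an iterable of numbers as CountedFloats sharing ``counter``."""
    return tuple(CountedFloat(v, counter) for v in values)
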