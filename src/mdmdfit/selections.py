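"""Residue-range selection grammar, parsed in exactly one place.

Selections are compact strings like ``"1-7,66-72"`` (inclusive ranges,
comma-separated, single residues allowed: ``"26,44,45"``).  An optional
chain prefix applies to the whole selection: ``"A:1-7,66-72"``.
"""

from __future__ import annotations


class SelectionSyntaxError(ValueError):
    pass


def parse_residue_ranges(spec: str) -> list[int]:
    """Expand ``"1-7,66-72"`` into a sorted list of residue ids."""
    chain, _, body = spec.partition(":") if ":" in spec else ("", "", spec)
    out: set[int] = set()
    for token in body.split(","):
        token = token.strip()
        if not token:
            continue
        lo, sep, hi = token.partition("-")
        try:
            if sep:
                lo_i, hi_i = int(lo), int(hi)
                if hi_i < lo_i:
                    raise SelectionSyntaxError(
                        f"descending range {token!r} in {spec!r}")
                out.update(range(lo_i, hi_i + 1))
            else:
                out.add(int(token))
        except ValueError as exc:
            raise SelectionSyntaxError(
                f"cannot parse residue token {token!r} in {spec!r}") from exc
    if not out:
        raise SelectionSyntaxError(f"empty selection {spec!r}")
    return sorted(out)


def parse_selection(spec: str) -> dict:
    """Parse ``"[CHAIN:]ranges"`` into Structure.mask criteria."""
    crit: dict = {}
    if ":" in spec:
        chain, _, body = spec.partition(":")
        if chain:
            crit["chains"] = [chain]
    else:
        body = spec
    crit["resids"] = parse_residue_ranges(body)
    return crit
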