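"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity by exhaustive enumeration (every
single-base substitution; every deletion window; every ordered mutation path
through the initiation graph) rather than sharing code with the package.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}


def brute_substitution_multiplicity(bases: str, coding_length: int) -> int:
    """Enumerate all single-base substitutions position by position.

    Counts each substitution that turns a non-stop codon into a stop codon,
    over positions 3 .. coding_length (skipping the initiator codon and any
    terminal stop, which lies beyond ``coding_length``).
    """
    raw = 0
    for i in range(3, coding_length):
        for alt in "ACGT":
            if alt == bases[i]:
                continue
            mutant = bases[:i] + alt + bases[i + 1 :]
            c = 3 * (i // 3)
            if mutant[c : c + 3] in STOPS and bases[c : c + 3] not in STOPS:
                raw += 1
    return raw


def brute_deletion_sensitive(bases: str, coding_length: int, k: int) -> int:
    """Exhaustively delete every length-k window and rescan the junction.

    Builds the full codon list of each re-joined mutant and flags a start
    position as sensitive when a codon overlapping the junction (codon
    floor(i/3), plus the next codon for frameshifting k) is a stop that was
    not a stop at the same codon index originally.  A junction codon drawn
    wholly from the original terminal stop region is the normal stop shifted
    forward (an in-frame truncation), not a nonsense gain.
    """
    orig_codons = [bases[c : c + 3] for c in range(0, len(bases) - 2, 3)]
    count = 0
    for i in range(0, coding_length - k + 1):
        mutant = bases[:i] + bases[i + k :]
        mut_codons = [mutant[c : c + 3] for c in range(0, len(mutant) - 2, 3)]
        junction = [i // 3] + ([i // 3 + 1] if k % 3 else [])
        for j in junction:
            if j >= len(mut_codons) or len(mut_codons[j]) < 3:
                continue
            origins = [q if q < i else q + k for q in range(3 * j, 3 * j + 3)]
            if min(origins) >= coding_length:
                continue
            was_stop = j < len(orig_codons) and orig_codons[j] in STOPS
            if mut_codons[j] in STOPS and not was_stop:
                count += 1
                break
    return count


def brute_longest_orf(bases: str) -> tuple[int, int, bool] | None:
    """(start, length, has_stop) of the longest ATG..stop ORF, ties by start."""
    best = None
    for start in range(len(bases) - 2):
        if bases[start : start + 3] != "ATG":
            continue
        j = start
        has_stop = False
        while j + 3 <= len(bases):
            if bases[j : j + 3] in STOPS:
                j += 3
                has_stop = True
                break
            j += 3
        length = j - start
        if best is None or length > best[1]:
            best = (start, length, has_stop)
    return best


def symbolic_path_coefficients():
    """Cubic coefficients of P1, P2, P3 by symbolic ordered-path enumeration.

    In the small-rate limit every three-step path WT -> x -> y -> end node
    contributes (product of its three rates) * N0 t^3 / 3!.  Returns the
    per-(N0 t^3) coefficients as sympy expressions in the four rate symbols.
    """
    import sympy as sp

    from schwannoma.incidence import EMISSIONS, TRANSITIONS

    syms = {
        name: sp.Symbol(name, positive=True)
        for name in ("mu_nf2", "mu_smarcb1", "mu_gfx", "r_loh")
    }
    edges: dict[str, list[tuple[str, "sp.Expr"]]] = {}
    for src, dst, coeff, rate in TRANSITIONS:
        edges.setdefault(src, []).append((dst, sp.nsimplify(coeff) * syms[rate]))
    coeffs = {}
    for end, terms in EMISSIONS.items():
        total = sp.Integer(0)
        for state, coeff, rate in terms:
            emission = sp.nsimplify(coeff) * syms[rate]
            for mid, r1 in edges["WT"]:
                for dst, r2 in edges.get(mid, []):
                    if dst == state:
                        total += r1 * r2 * emission
        coeffs[end] = sp.simplify(total / sp.factorial(3))
    return syms, coeffs
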