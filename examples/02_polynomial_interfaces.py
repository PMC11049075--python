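"""Polynomial interfaces: Markov blankets, tensor, hom, currying.

A polynomial p = Σ_i y^{p[i]} records an agent's configurations
(positions) and the sense data admissible in each (directions).
"""

from protentia.categorical import FiniteSet
from protentia.poly import (
    curry_check,
    enumerate_morphisms,
    hom,
    identity_poly,
    make_monomial,
    tensor,
    total_set,
)

# The classical Markov blanket is a monomial: every action sees the same senses.
actions = FiniteSet(["approach", "avoid"])
senses = FiniteSet(["bright", "dim", "dark"])
blanket = make_monomial(actions, senses)
print(f"Blanket A·y^S: {len(blanket.positions)} configurations, "
      f"|Σp| = {len(total_set(blanket))} (= |A|·|S| = {len(actions)*len(senses)})")

# Tensor places two agents side by side: joint configurations and joint senses.
joint = tensor(blanket, blanket)
print(f"Two agents tensored: {len(joint.positions)} joint configurations, "
      f"{len(joint.directions[joint.positions.labels[0]])} joint sense data each")

# Morphisms p -> y are the environment's possible responses (sections).
y = identity_poly()
sections = enumerate_morphisms(blanket, y)
print(f"Morphisms blanket -> y: {len(sections)} "
      f"(= |S|^|A| = {len(senses)**len(actions)} choice functions)")

# The hom polynomial internalizes patterns of interaction; [y, q] recovers q.
print(f"hom(y, blanket) profile == blanket profile: "
      f"{hom(y, blanket).profile() == blanket.profile()}")

# Currying: predicting a partner-and-world pattern is the same as predicting
# the world jointly with the partner: [p,[q,r]] ≅ [p⊗q, r].
p = make_monomial(FiniteSet(["a"]), FiniteSet(["x", "y"]))
q = make_monomial(FiniteSet(["b1", "b2"]), FiniteSet(["z"]))
rep = curry_check(p, q, y)
print(f"curry check [p,[q,y]] vs [p⊗q,y]: isomorphic={rep.isomorphic}, "
      f"{rep.lhs_positions} positions on both sides")
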