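"""Evaluator pipelines: piecewise branches and argument binding.

g(n) selects 7.1, 100 or the free argument x by the ensemble member n.
A reference evaluator then binds x to the constant k1 = 0.331, defining
f(n) = g(n) such that x = k1.  A second pipeline binds a function-valued
argument h to the identity, making its h(29) branch evaluate to 29.
"""
from fieldml import (build_binding_demo, build_function_binding_demo,
                     evaluate, evaluate_with_binding)
from fieldml.evaluate import Environment, EnsembleValue


def env_for(demo, member):
    ens = demo.n_argument.value_type
    return Environment({demo.n_argument: EnsembleValue(ens, member)})


demo = build_binding_demo()
print("g-branch values through f:")
for n in (1, 2):
    print(f"  f({n}) = {evaluate(demo.f, env_for(demo, n)).scalar}")
print(f"  f(3) = {evaluate_with_binding(demo.f, env_for(demo, 3)).scalar}"
      "   <- the bound constant k1")

fdemo = build_function_binding_demo()
print(f"function binding: f(3) = "
      f"{evaluate(fdemo.f, env_for(fdemo, 3)).scalar}"
      "   <- identity applied to the operand 29")
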