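"""How likely is a community to adopt a variant carried by its migrants?

Evaluates the frequency-dependent adoption probability
p = k^(1-beta) / (k^(1-beta) + (n-k)^(1-beta)) for a community of n = 100
residents as the number of discordant migrants k grows, under neutral
frequency dependence (beta = 0) and strong conformity (beta = -10).
"""

from hitchsim import adoption_probability

n = 100
print(f"community size n = {n}")
print(f"{'k':>4} {'beta=0':>12} {'beta=-10':>12}")
for k in (1, 5, 10, 25, 50, 75, 99):
    p0 = adoption_probability(k, n, 0.0)
    p10 = adoption_probability(k, n, -10.0)
    print(f"{k:>4} {p0:>12.4g} {p10:>12.4g}")

print(
    "\nAt beta=0 the flip probability equals the discordant share k/n "
    "(one migrant in 100 -> 0.01 per step); at beta=-10 adoption is "
    "essentially impossible until migrants are the majority, which is why "
    "that regime models the absence of intergroup adoption."
)
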