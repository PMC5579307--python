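# Reference IR3535 / nonanoic acid equilibrium at 50 degC (323.15 K).
# The Redlich-Kister coefficients are calibrated so that the equilibrium
# curve crosses y = x at exactly 10 and 77 mol% IR3535, the 77 mol%
# crossing being the bubble-pressure minimum (negative azeotrope,
# attractor under open evaporation).  Antoine constants are a
# phenomenological stand-in pinned to 8.0 Pa (IR3535) and 11.6 Pa
# (nonanoic acid) at 323.15 K, so the neat acid loses mass faster.
components:
  a:
    name: IR3535
    molar_mass: 215.29
    antoine: [30.54919243135955, 9200.0, 0.0]
    t_range: [290.0, 400.0]
  b:
    name: nonanoic acid
    molar_mass: 158.24
    antoine: [28.754579289664232, 8500.0, 0.0]
    t_range: [290.0, 400.0]
activity:
  coefficients: [-0.73743208192254, -3.100245621979251, -2.4464596367993163,
                 -1.7890781107881342, 2.9756389620395813, 5.005819494359955,
                 0.8388248134438583, -1.9773316846750202]
temperature: 323.15
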