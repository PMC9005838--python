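# Full factorial grid of odd-function (nonlinear-family) miscalibration
# scenarios: a in {0, 1/4, 1/2} x b in {1/3, 2/3, 1, 4/3, 5/3} x n in {100, 250, 1000}.
scenarios:
  - {family: nonlinear, a: 0.0, b: 0.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.0, b: 0.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.0, b: 0.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.0, b: 0.6666666666666666, n: 100}
  - {family: nonlinear, a: 0.0, b: 0.6666666666666666, n: 250}
  - {family: nonlinear, a: 0.0, b: 0.6666666666666666, n: 1000}
  - {family: nonlinear, a: 0.0, b: 1.0, n: 100}
  - {family: nonlinear, a: 0.0, b: 1.0, n: 250}
  - {family: nonlinear, a: 0.0, b: 1.0, n: 1000}
  - {family: nonlinear, a: 0.0, b: 1.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.0, b: 1.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.0, b: 1.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.0, b: 1.6666666666666667, n: 100}
  - {family: nonlinear, a: 0.0, b: 1.6666666666666667, n: 250}
  - {family: nonlinear, a: 0.0, b: 1.6666666666666667, n: 1000}
  - {family: nonlinear, a: 0.25, b: 0.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.25, b: 0.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.25, b: 0.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.25, b: 0.6666666666666666, n: 100}
  - {family: nonlinear, a: 0.25, b: 0.6666666666666666, n: 250}
  - {family: nonlinear, a: 0.25, b: 0.6666666666666666, n: 1000}
  - {family: nonlinear, a: 0.25, b: 1.0, n: 100}
  - {family: nonlinear, a: 0.25, b: 1.0, n: 250}
  - {family: nonlinear, a: 0.25, b: 1.0, n: 1000}
  - {family: nonlinear, a: 0.25, b: 1.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.25, b: 1.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.25, b: 1.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.25, b: 1.6666666666666667, n: 100}
  - {family: nonlinear, a: 0.25, b: 1.6666666666666667, n: 250}
  - {family: nonlinear, a: 0.25, b: 1.6666666666666667, n: 1000}
  - {family: nonlinear, a: 0.5, b: 0.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.5, b: 0.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.5, b: 0.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.5, b: 0.6666666666666666, n: 100}
  - {family: nonlinear, a: 0.5, b: 0.6666666666666666, n: 250}
  - {family: nonlinear, a: 0.5, b: 0.6666666666666666, n: 1000}
  - {family: nonlinear, a: 0.5, b: 1.0, n: 100}
  - {family: nonlinear, a: 0.5, b: 1.0, n: 250}
  - {family: nonlinear, a: 0.5, b: 1.0, n: 1000}
  - {family: nonlinear, a: 0.5, b: 1.3333333333333333, n: 100}
  - {family: nonlinear, a: 0.5, b: 1.3333333333333333, n: 250}
  - {family: nonlinear, a: 0.5, b: 1.3333333333333333, n: 1000}
  - {family: nonlinear, a: 0.5, b: 1.6666666666666667, n: 100}
  - {family: nonlinear, a: 0.5, b: 1.6666666666666667, n: 250}
  - {family: nonlinear, a: 0.5, b: 1.6666666666666667, n: 1000}
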