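complex_id,e_ele,e_nonele,e_other,predicted,experimental_dg
1UK0,-27.60,-31.85,-1.51,-9.47,-10.80
2RD6,-27.05,-37.99,0.12,-9.33,
3GN7,-21.43,-38.54,-1.28,-9.64,
3L3M,-16.65,-48.90,0.07,-9.78,
4GV7,-3.40,-32.29,-1.71,-7.98,-7.46
4HHY,-24.67,-45.16,-3.04,-11.35,-11.89
4HHZ,-11.12,-42.76,-2.97,-10.16,-10.53
4L6S,-56.25,-40.28,-1.47,-12.24,-11.62
4OPX,-7.78,-27.32,-1.53,-7.68,-7.77
4OQA,-1.74,-30.47,-2.54,-8.06,-8.35
4OQB,-8.30,-21.89,-2.37,-7.53,-7.75
4R5W,-8.32,-43.07,-1.75,-9.45,
4R6E,-33.44,-50.87,0.08,-11.11,
4RV6,-36.45,-38.64,0.62,-9.79,
4UND,-8.50,-37.30,-1.67,-8.83,
4UXB,-15.81,-37.64,4.25,-6.65,
4ZZZ,-3.87,-35.54,-1.81,-8.40,-7.19
5A00,-32.98,-45.02,1.68,-9.74,-10.37
5HA9,-25.28,-20.94,-2.15,-8.47,
5KPN,-21.31,-51.57,-1.94,-11.29,
5KPO,-20.21,-52.82,-1.96,-11.36,
5KPP,-15.33,-54.20,-1.79,-11.10,
5KPQ,-12.84,-50.57,-2.14,-10.71,
5WRQ,-52.56,-47.39,-2.40,-13.16,
5WRY,-49.05,-54.66,-1.85,-13.43,
5WRZ,-31.97,-34.18,1.15,-8.78,
5WS0,-37.67,-38.08,-0.68,-10.41,-10.06
5WS1,-35.74,-39.50,-1.86,-10.97,-10.67
5WTC,-16.65,-52.36,-1.63,-10.92,
5XSR,-39.98,-43.86,1.56,-10.14,-10.59
5XST,-40.52,-51.08,2.02,-10.72,-10.32
5XSU,-32.63,-40.62,2.60,-8.84,-9.02
6GHK,-4.84,-50.47,-1.82,-10.02,
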