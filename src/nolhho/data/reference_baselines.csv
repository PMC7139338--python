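function,metric,GA,PSO,BBO,FPA,GWO,BAT,FA,MFO,DE
F1,AVG,1.03E+03,1.83E+04,7.59E+01,2.01E+03,1.18E-27,6.59E+04,7.11E-03,1.01E+03,1.33E-03
F1,STD,5.79E+02,3.01E+03,2.75E+01,5.60E+02,1.47E-27,7.51E+03,3.21E-03,3.05E+03,5.92E-04
F2,AVG,2.47E+01,3.58E+02,1.36E-03,3.22E+01,9.71E-17,2.71E+08,4.34E-01,3.19E+01,6.83E-03
F2,STD,5.68E+00,1.35E+03,7.45E-03,5.55E+00,5.60E-17,1.30E+09,1.84E-01,2.06E+01,2.06E-03
F3,AVG,2.65E+04,4.05E+04,1.21E+04,1.41E+03,5.12E-05,1.38E+05,1.66E+03,2.43E+04,3.97E+04
F3,STD,3.44E+03,8.21E+03,2.69E+03,5.59E+02,2.03E-04,4.72E+04,6.72E+02,1.41E+04,5.37E+03
F4,AVG,5.17E+01,4.39E+01,3.02E+01,2.38E+01,1.24E-06,8.51E+01,1.11E-01,7.00E+01,1.15E+01
F4,STD,1.05E+01,3.64E+00,4.39E+00,2.77E+00,1.94E-06,2.95E+00,4.75E-02,7.06E+00,2.37E+00
F5,AVG,1.95E+04,1.96E+07,1.82E+03,3.17E+05,2.70E+01,2.10E+08,7.97E+01,7.35E+03,1.06E+02
F5,STD,1.31E+04,6.25E+06,9.40E+02,1.75E+05,7.78E-01,4.17E+07,7.39E+01,2.26E+04,1.01E+02
F6,AVG,9.01E+02,1.87E+04,6.71E+01,1.70E+03,8.44E-01,6.69E+04,6.94E-03,2.68E+03,1.44E-03
F6,STD,2.84E+02,2.92E+03,2.20E+01,3.13E+02,3.18E-01,5.87E+03,3.61E-03,5.84E+03,5.38E-04
F7,AVG,1.91E-01,1.07E+01,2.91E-03,3.41E-01,1.70E-03,4.57E+01,6.62E-02,4.50E+00,5.24E-02
F7,STD,1.50E-01,3.05E+00,1.83E-03,1.10E-01,1.06E-03,7.82E+00,4.23E-02,9.21E+00,1.37E-02
F8,AVG,-1.26E+04,-3.86E+03,-1.24E+04,-6.45E+03,-5.97E+03,-2.33E+03,-5.85E+03,-8.48E+03,-6.82E+03
F8,STD,4.51E+00,2.49E+02,3.50E+01,3.03E+02,7.10E+02,2.96E+02,1.16E+03,7.98E+02,3.94E+02
F9,AVG,9.04E+00,2.87E+02,0.00E+00,1.82E+02,2.19E+00,1.92E+02,3.82E+01,1.59E+02,1.58E+02
F9,STD,4.58E+00,1.95E+01,0.00E+00,1.24E+01,3.69E+00,3.56E+01,1.12E+01,3.21E+01,1.17E+01
F10,AVG,1.36E+01,1.75E+01,2.13E+00,7.14E+00,1.03E-13,1.92E+01,4.58E-02,1.74E+01,1.21E-02
F10,STD,1.51E+00,3.67E-01,3.53E-01,1.08E+00,1.70E-14,2.43E-01,1.20E-02,4.95E+00,3.30E-03
F11,AVG,1.01E+01,1.70E+02,1.46E+00,1.73E+01,4.76E-03,6.01E+02,4.23E-03,3.10E+01,3.52E-02
F11,STD,2.43E+00,3.17E+01,1.69E-01,3.63E+00,8.57E-03,5.50E+01,1.29E-03,5.94E+01,7.20E-02
F12,AVG,4.77E+00,1.51E+07,6.68E-01,3.05E+02,4.83E-02,4.71E+08,3.13E-04,2.46E+02,2.25E-03
F12,STD,1.56E+00,9.88E+06,2.62E-01,1.04E+03,2.12E-02,1.54E+08,1.76E-04,1.21E+03,1.70E-03
F13,AVG,1.52E+01,5.73E+07,1.82E+00,9.59E+04,5.96E-01,9.40E+08,2.08E-03,2.73E+07,9.12E-03
F13,STD,4.52E+00,2.68E+07,3.41E-01,1.46E+05,2.23E-01,1.67E+08,9.62E-04,1.04E+08,1.16E-02
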