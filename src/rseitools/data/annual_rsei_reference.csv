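year,NDVI,TCW,NDBSI,LST,contribution_rate,rsei_mean
2000,-0.43,-0.59,0.67,0.12,84.72,0.52
2001,-0.44,-0.52,0.61,0.38,70.03,0.54
2002,-0.45,-0.58,0.65,0.16,87.24,0.56
2003,-0.42,-0.57,0.65,0.26,86.22,0.55
2004,-0.43,-0.51,0.58,0.45,75.37,0.55
2005,-0.37,-0.54,0.61,0.43,70.11,0.54
2006,-0.31,-0.54,0.61,0.48,75.65,0.52
2007,-0.34,-0.53,0.60,0.47,74.99,0.54
2008,-0.32,-0.54,0.60,0.48,75.11,0.51
2009,-0.29,-0.55,0.61,0.47,75.35,0.52
2010,-0.24,-0.60,0.66,0.35,66.32,0.51
2011,-0.23,-0.57,0.63,0.45,73.46,0.50
2012,-0.50,-0.56,0.61,0.23,86.4,0.55
2013,-0.46,-0.52,0.57,0.42,79.47,0.52
2014,-0.46,-0.51,0.56,0.44,82.79,0.54
2015,-0.47,-0.53,0.57,0.40,78.91,0.55
2016,-0.45,-0.54,0.57,0.40,78.08,0.58
2017,-0.46,-0.52,0.56,0.43,82.9,0.55
2018,-0.44,-0.53,0.56,0.44,81.12,0.53
2019,-0.45,-0.53,0.56,0.43,81.2,0.54
2020,-0.47,-0.52,0.56,0.43,83.52,0.56
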