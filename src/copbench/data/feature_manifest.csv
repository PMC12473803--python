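name,domain,axis,description
Mean distance,positional,planar,Mean resultant distance of the centered CoP from its centroid
Mean distance ML,positional,ML,Mean absolute medio-lateral excursion of the centered CoP
Mean distance AP,positional,AP,Mean absolute anterior-posterior excursion of the centered CoP
Root mean square ML,positional,ML,Root-mean-square sway along the medio-lateral axis
Root mean square AP,positional,AP,Root-mean-square sway along the anterior-posterior axis
Root mean square ML-AP,positional,ML-AP,Root-mean-square resultant sway distance
Maximal distance (Radius),positional,planar,Largest resultant distance of the centered CoP from its centroid
Maximal distance ML,positional,ML,Largest absolute medio-lateral excursion from the centroid
Maximal distance AP,positional,AP,Largest absolute anterior-posterior excursion from the centroid
Range ML,positional,ML,Peak-to-peak medio-lateral CoP excursion
Range AP,positional,AP,Peak-to-peak anterior-posterior CoP excursion
Range ML-AP,positional,ML-AP,Largest distance between any two CoP samples in the plane
95% confidence ellipse area,positional,planar,Area of the 95% covariance confidence ellipse of the CoP cloud
Principal sway direction,positional,planar,Orientation in degrees of the leading covariance eigenvector
Planar deviation,positional,planar,Square root of the summed per-axis CoP variances
Mean Velocity ML,dynamic,ML,Mean absolute medio-lateral CoP velocity
Mean Velocity AP,dynamic,AP,Mean absolute anterior-posterior CoP velocity
Mean Velocity ML-AP,dynamic,ML-AP,Mean resultant CoP speed (path length per second)
Mean positive peak velocity ML,dynamic,ML,Mean of positive local maxima of the signed ML velocity
Mean positive peak velocity AP,dynamic,AP,Mean of positive local maxima of the signed AP velocity
Mean negative peak velocity ML,dynamic,ML,Mean of negative local minima of the signed ML velocity
Mean negative peak velocity AP,dynamic,AP,Mean of negative local minima of the signed AP velocity
Velocity standard deviation ML,dynamic,ML,Standard deviation of the signed ML velocity
Velocity standard deviation AP,dynamic,AP,Standard deviation of the signed AP velocity
Velocity standard deviation ML-AP,dynamic,ML-AP,Standard deviation of the resultant CoP speed
Sway area per second ML-AP,dynamic,ML-AP,Area swept by the centered position vector per unit time
Phase plane parameter ML,dynamic,ML,Combined position and velocity dispersion along ML
Phase plane parameter AP,dynamic,AP,Combined position and velocity dispersion along AP
Mean frequency ML,dynamic,ML,Velocity-based oscillation frequency of the ML sway
Mean frequency AP,dynamic,AP,Velocity-based oscillation frequency of the AP sway
Mean frequency ML-AP,dynamic,ML-AP,Rotational frequency of the resultant sway vector
Total power (Power Spectrum Density) ML,frequency,ML,Integrated spectral power of the ML CoP signal
Mean frequency (Power Spectrum Density) ML,frequency,ML,Power-weighted mean frequency of the ML spectrum
Centroidal frequency (Power Spectrum Density) ML,frequency,ML,Root of the second spectral moment ratio for ML
Mode of Power Spectrum Density ML,frequency,ML,Frequency of the ML spectral peak
50% Power Frequency ML,frequency,ML,Frequency below which half of the ML power lies
95% Power Frequency ML,frequency,ML,Frequency below which 95% of the ML power lies
Frequency Quotient Power Spectrum Density ML,frequency,ML,Ratio of high-band to low-band ML spectral power
Energy content below 0.5 Hz (Power Spectrum Density) ML,frequency,ML,Fraction of ML power at or below 0.5 Hz
Energy content 0.5-2 Hz (Power Spectrum Density) ML,frequency,ML,Fraction of ML power between 0.5 and 2 Hz
Energy content above 2 Hz (Power Spectrum Density) ML,frequency,ML,Fraction of ML power above 2 Hz
Total power (Power Spectrum Density) AP,frequency,AP,Integrated spectral power of the AP CoP signal
Mean frequency (Power Spectrum Density) AP,frequency,AP,Power-weighted mean frequency of the AP spectrum
Centroidal frequency (Power Spectrum Density) AP,frequency,AP,Root of the second spectral moment ratio for AP
Mode of Power Spectrum Density AP,frequency,AP,Frequency of the AP spectral peak
50% Power Frequency AP,frequency,AP,Frequency below which half of the AP power lies
95% Power Frequency AP,frequency,AP,Frequency below which 95% of the AP power lies
Frequency Quotient Power Spectrum Density AP,frequency,AP,Ratio of high-band to low-band AP spectral power
Energy content below 0.5 Hz (Power Spectrum Density) AP,frequency,AP,Fraction of AP power at or below 0.5 Hz
Energy content 0.5-2 Hz (Power Spectrum Density) AP,frequency,AP,Fraction of AP power between 0.5 and 2 Hz
Energy content above 2 Hz (Power Spectrum Density) AP,frequency,AP,Fraction of AP power above 2 Hz
Short-term diffusion coefficient ML,stochastic,ML,Half-slope of the short-term linear MSD fit along ML
Long-term diffusion coefficient ML,stochastic,ML,Half-slope of the long-term linear MSD fit along ML
Critical time ML,stochastic,ML,Lag at the intersection of the short- and long-term ML fits
Critical displacement ML,stochastic,ML,Squared displacement at the ML critical point
Short-term scaling exponent ML,stochastic,ML,Half log-log MSD slope in the short-term ML window
Long-term scaling exponent ML,stochastic,ML,Half log-log MSD slope in the long-term ML window
Fractal dimension ML,stochastic,ML,Fractal dimension derived from the short-term ML scaling exponent
Short-term diffusion coefficient AP,stochastic,AP,Half-slope of the short-term linear MSD fit along AP
Long-term diffusion coefficient AP,stochastic,AP,Half-slope of the long-term linear MSD fit along AP
Critical time AP,stochastic,AP,Lag at the intersection of the short- and long-term AP fits
Critical displacement AP,stochastic,AP,Squared displacement at the AP critical point
Short-term scaling exponent AP,stochastic,AP,Half log-log MSD slope in the short-term AP window
Long-term scaling exponent AP,stochastic,AP,Half log-log MSD slope in the long-term AP window
Fractal dimension AP,stochastic,AP,Fractal dimension derived from the short-term AP scaling exponent
Short-term diffusion coefficient ML-AP,stochastic,ML-AP,Quarter-slope of the short-term linear planar MSD fit
Long-term diffusion coefficient ML-AP,stochastic,ML-AP,Quarter-slope of the long-term linear planar MSD fit
Critical time ML-AP,stochastic,ML-AP,Lag at the intersection of the short- and long-term planar fits
Critical displacement ML-AP,stochastic,ML-AP,Squared displacement at the planar critical point
Short-term scaling exponent ML-AP,stochastic,ML-AP,Half log-log planar MSD slope in the short-term window
Long-term scaling exponent ML-AP,stochastic,ML-AP,Half log-log planar MSD slope in the long-term window
Fractal dimension ML-AP,stochastic,ML-AP,Fractal dimension derived from the planar short-term scaling exponent
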